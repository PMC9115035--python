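import numpy as np
import pytest

from ironcycle import build_world
from ironcycle.agents import BOUND_OXIDIZER, BOUND_REDUCER, FREE, random_unit_vectors
from ironcycle.config import WorldConfig
from ironcycle.exchange import (
    aging_step,
    dissociate_from_oxidizer,
    dissociate_from_reducer,
    dissociation_step,
    equilibrate,
    np_loss,
    update_aging,
)


def make_world(**kw):
    base = dict(
        grid_side=5, fe_patch_percentage=0.0, initial_number_fe3reducer=0,
        initial_number_fe2oxidizer=0, initial_number_nanoparticle=0,
        max_ticks=10, np_loss_percentage=0.0,
    )
    base.update(kw)
    return build_world(WorldConfig(**base), seed=13)


class TestDissociationRules:
    @pytest.mark.parametrize("frac2,threshold,freed", [
        (0.71, 0.7, True),
        (0.70, 0.7, False),  # strict inequality
        (0.99, 1.0, False),  # threshold 1 -> never freed
    ])
    def test_reducer_release_threshold(self, frac2, threshold, freed):
        assert dissociate_from_reducer(frac2, threshold) is freed

    def test_shedding_probability_half_at_the_shedding_diameter(self):
        rng = np.random.default_rng(0)
        n = 4000
        shed = sum(dissociate_from_oxidizer(10.0, 10.0, rng) for _ in range(n)) / n
        assert shed == pytest.approx(0.5, abs=0.03)

    def test_shedding_probability_two_sd_below(self):
        rng = np.random.default_rng(0)
        n = 20_000
        shed = sum(dissociate_from_oxidizer(6.0, 10.0, rng) for _ in range(n)) / n
        assert shed == pytest.approx(0.0228, abs=0.006)

    def test_degenerate_spread_sheds_deterministically(self):
        rng = np.random.default_rng(0)
        assert dissociate_from_oxidizer(10.1, 10.0, rng, sd=0.0)
        assert not dissociate_from_oxidizer(9.9, 10.0, rng, sd=0.0)


class TestDissociationStep:
    def test_passivated_particle_leaves_the_reducer(self):
        from ironcycle.agents import Reducer

        w = make_world()
        r = Reducer(position=np.full(3, 2.5), heading=np.array([1.0, 0, 0]))
        w.reducers.append(r)
        i = w.nps.add(fe3=2.0, fe2=8.0, pos=r.position.copy(),
                      heading=np.array([1.0, 0, 0]),
                      bound_kind=BOUND_REDUCER, host=0)
        j = w.nps.add(fe3=8.0, fe2=2.0, pos=r.position.copy(),
                      heading=np.array([1.0, 0, 0]),
                      bound_kind=BOUND_REDUCER, host=0)
        r.bound_nps.extend([i, j])
        dissociation_step(w)
        assert w.nps.bound_kind[i] == FREE
        assert w.nps.bound_kind[j] == BOUND_REDUCER
        assert r.bound_nps == [j]

    def test_shedding_statistics_recorded(self):
        from ironcycle.agents import Oxidizer, np_iron_from_diameter

        w = make_world()
        o = Oxidizer(position=np.full(3, 2.5), heading=np.array([1.0, 0, 0]))
        w.oxidizers.append(o)
        iron = np_iron_from_diameter(30.0, w.cfg.iron_per_cubicnm, w.cfg.unit_scale)
        i = w.nps.add(fe3=iron, fe2=0.0, pos=o.position.copy(),
                      heading=np.array([1.0, 0, 0]),
                      bound_kind=BOUND_OXIDIZER, host=0)
        o.surface_nps.append(i)
        dissociation_step(w)  # d=30 >> 10: sheds with overwhelming probability
        assert w.nps.bound_kind[i] == FREE
        assert o.surface_nps == []
        assert w.shed_count == 1
        assert w.shed_diameter_sum == pytest.approx(30.0)


class TestEquilibration:
    def single_solid_world(self, dissolved=1000.0):
        w = make_world(grid_side=3, start_medium_fe2=dissolved)
        w.is_bulk[1, 1, 1] = True
        w.cluster_id[1, 1, 1] = 0
        w.fe3[1, 1, 1] = 0.0
        w._finalise_lattice()
        return w

    def test_single_solid_transfer_matches_closed_form_first_step(self):
        # A=0, D=1000, ineq=0.9, rate=0.02: target 900, transfer 18
        w = self.single_solid_world()
        equilibrate(w)
        assert w.fe2_ads[1, 1, 1] == pytest.approx(18.0)
        assert w.dissolved_fe2 == pytest.approx(982.0)

    @pytest.mark.parametrize("n", [1, 10, 150])
    def test_residual_decays_as_one_minus_rate_to_the_n(self, n):
        w = self.single_solid_world()
        rate = w.cfg.fe2_equilibrium_rate
        for _ in range(n):
            equilibrate(w)
        residual = 900.0 - w.fe2_ads[1, 1, 1]
        assert residual == pytest.approx(900.0 * (1 - rate) ** n, rel=1e-9)

    def test_equilibrium_is_a_fixed_point(self):
        w = self.single_solid_world()
        w.fe2_ads[1, 1, 1] = 900.0
        w.dissolved_fe2 = 100.0
        equilibrate(w)
        assert w.fe2_ads[1, 1, 1] == pytest.approx(900.0)
        assert w.dissolved_fe2 == pytest.approx(100.0)

    def test_global_conservation_with_patches_and_particles(self):
        w = make_world(grid_side=5, fe_patch_percentage=20.0,
                       start_medium_fe2=5000.0)
        for k in range(10):
            w.nps.add(fe3=10.0, fe2=float(k), pos=w.random_medium_position(),
                      heading=random_unit_vectors(w.rng, 1)[0])
        w.fe2_ads[w.is_bulk] = w.rng.random(int(w.is_bulk.sum())) * 400
        total = w.iron_total()
        for _ in range(25):
            equilibrate(w)
        assert w.iron_total() == pytest.approx(total, rel=1e-12)
        assert w.dissolved_fe2 >= 0

    def test_overdraw_is_clamped(self):
        w = self.single_solid_world(dissolved=1.0)
        w.fe2_ads[1, 1, 1] = 0.0
        w.cfg = w.cfg.with_overrides(fe2_equilibrium_rate=1.0)
        equilibrate(w)  # wants 0.9*(0+1)=0.9 of a 1-unit pool
        assert w.dissolved_fe2 >= 0.0


class TestNpLoss:
    def test_zero_percentage_removes_nothing(self):
        w = make_world(np_loss_percentage=0.0)
        for _ in range(20):
            w.nps.add(fe3=1.0, fe2=0.0, pos=w.random_medium_position(),
                      heading=random_unit_vectors(w.rng, 1)[0])
        assert np_loss(w) == 0
        assert w.nps.count == 20

    def test_full_percentage_removes_all_free_but_no_bound(self):
        from ironcycle.agents import Reducer

        w = make_world(np_loss_percentage=100.0)
        r = Reducer(position=np.full(3, 2.5), heading=np.array([1.0, 0, 0]))
        w.reducers.append(r)
        for _ in range(10):
            w.nps.add(fe3=1.0, fe2=0.0, pos=w.random_medium_position(),
                      heading=random_unit_vectors(w.rng, 1)[0])
        b = w.nps.add(fe3=1.0, fe2=0.0, pos=r.position.copy(),
                      heading=np.array([1.0, 0, 0]),
                      bound_kind=BOUND_REDUCER, host=0)
        r.bound_nps.append(b)
        total = w.iron_total()
        assert np_loss(w) == 10
        assert w.nps.count == 1
        assert w.removed_iron == pytest.approx(10.0)
        assert w.iron_total() == pytest.approx(total)  # ledger closes the balance

    def test_expected_binomial_mean(self):
        w = make_world(np_loss_percentage=0.2)
        for _ in range(1000):
            w.nps.add(fe3=1.0, fe2=0.0, pos=w.random_medium_position(),
                      heading=random_unit_vectors(w.rng, 1)[0])
        removed = sum(np_loss(w) for _ in range(50))
        # ~2 per tick from 1000 particles at 0.2%
        assert removed == pytest.approx(50 * 2, abs=30)


class TestAging:
    @pytest.mark.parametrize("clock,expected", [
        (200, 1.0),    # lag boundary: decay has not started
        (300, 0.7),    # 1 - 0.003 * 100
        (534, 0.0),    # clamped at zero
        (10_000, 0.0),
    ])
    def test_linear_decay_after_lag(self, clock, expected):
        assert update_aging(clock, 200, 0.003) == pytest.approx(expected, abs=1e-9)

    def test_susceptibility_monotone_between_reductions(self):
        vals = [update_aging(t, 200, 0.003) for t in range(0, 700, 7)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert all(0.0 <= v <= 1.0 for v in vals)

    def test_clock_advances_each_tick(self):
        w = make_world()
        i = w.nps.add(fe3=1.0, fe2=0.0, pos=w.random_medium_position(),
                      heading=random_unit_vectors(w.rng, 1)[0])
        for _ in range(5):
            aging_step(w)
        assert w.nps.clock[i] == 5
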