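import numpy as np
import pytest

from ironcycle import build_world
from ironcycle.agents import BOUND_REDUCER, np_iron_from_diameter, random_unit_vectors
from ironcycle.config import WorldConfig
from ironcycle.redox import (
    abiotic_oxidation_step,
    biotic_oxidation_step,
    mtrc_occupancy,
    reduce_step,
)

from helpers import attach_reducer


def make_world(**kw):
    base = dict(
        grid_side=7, fe_patch_percentage=0.0, initial_number_fe3reducer=0,
        initial_number_fe2oxidizer=0, initial_number_nanoparticle=0,
        max_ticks=10, np_loss_percentage=0.0,
    )
    base.update(kw)
    return build_world(WorldConfig(**base), seed=11)


def add_agent(world, kind, patch):
    from ironcycle.agents import Oxidizer, Reducer

    cls = Reducer if kind == "reducer" else Oxidizer
    a = cls(position=np.asarray(patch, dtype=float) + 0.5,
            heading=random_unit_vectors(world.rng, 1)[0])
    (world.reducers if kind == "reducer" else world.oxidizers).append(a)
    return a


def bind_np_with_mtrc_fraction(world, r_idx, fraction):
    """Bind a fully ferric particle whose squared diameter over the cell
    surface area equals `fraction` (diameter fixes the iron content)."""
    cfg = world.cfg
    d = np.sqrt(fraction * cfg.cell_surface_area)
    iron = np_iron_from_diameter(d, cfg.iron_per_cubicnm, cfg.unit_scale)
    r = world.reducers[r_idx]
    i = world.nps.add(fe3=iron, fe2=0.0, pos=r.position.copy(),
                      heading=random_unit_vectors(world.rng, 1)[0],
                      bound_kind=BOUND_REDUCER, host=r_idx)
    r.bound_nps.append(i)
    return i


class TestMtrC:
    def test_printed_formula_with_default_surface(self):
        occupied, fraction = mtrc_occupancy(10.0, 3.5e6)
        assert occupied == pytest.approx(0.2857, rel=1e-3)
        assert fraction == pytest.approx(2.857e-5, rel=1e-3)

    def test_saturation_when_footprint_equals_area(self):
        _, fraction = mtrc_occupancy(np.sqrt(3.5e6), 3.5e6)
        assert fraction == pytest.approx(1.0)


class TestReduceStep:
    def test_attached_reducer_with_mineral_in_range_splits_80_20(self, small_world):
        w = small_world
        r = attach_reducer(w, tuple(w.bulk_coords[0]))
        w.oxic = False
        budget = reduce_step(w, r)
        rate = w.cfg.contact_reduction_rate
        assert budget.contact_reduced == pytest.approx(rate)
        assert budget.shuttle_reduced == pytest.approx(4.0 * rate)
        assert budget.total == pytest.approx(5.0 * rate)
        assert budget.shuttle_reduced / budget.total == pytest.approx(0.8)

    def test_unattached_no_particles_no_mineral_reduces_nothing(self):
        w = make_world()
        r = add_agent(w, "reducer", (1, 1, 1))
        w.oxic = False
        assert reduce_step(w, r).total == 0.0

    def test_bound_particle_reduction_follows_printed_formula(self):
        # MtrC fraction 0.01, ratio 100, rate 100 -> 100 units reduced at a
        # capacity charge of 1 unit; the shuttle then gets the remaining 399
        w = make_world()
        r = add_agent(w, "reducer", (1, 1, 1))
        i = bind_np_with_mtrc_fraction(w, 0, fraction=0.01)
        w.oxic = False
        fe3_before = w.nps.fe3[i]
        budget = reduce_step(w, r)
        assert budget.np_reduced == pytest.approx(100.0)
        assert w.nps.fe3[i] == pytest.approx(fe3_before - 100.0)
        assert w.nps.fe2[i] == pytest.approx(100.0)
        assert w.nps.clock[i] == 0

    def test_capacity_accounting_never_exceeds_four_contact_rates(self):
        w = make_world()
        attach = add_agent(w, "reducer", (1, 1, 1))
        # five particles each charging 0.9*rate against a capacity of 4*rate:
        # the shared budget must clip the sequence
        for _ in range(5):
            bind_np_with_mtrc_fraction(w, 0, fraction=0.9)
        w.oxic = False
        budget = reduce_step(w, attach)
        cap = 4.0 * w.cfg.contact_reduction_rate
        charge = budget.np_reduced / w.cfg.np_mineral_reduction_ratio
        assert charge + budget.shuttle_reduced <= cap + 1e-9
        assert charge == pytest.approx(cap)  # the cap binds

    def test_reduction_rejected_under_oxic_conditions(self, small_world):
        w = small_world
        w.oxic = True
        with pytest.raises(ValueError):
            reduce_step(w, w.reducers[0])

    def test_aged_particles_are_reduced_more_slowly(self):
        w = make_world(aging_enabled=True, aging_lag=200, aging_rate=0.003)
        r = add_agent(w, "reducer", (1, 1, 1))
        i = bind_np_with_mtrc_fraction(w, 0, fraction=0.01)
        w.nps.clock[i] = 300  # susceptibility 1 - 0.003*100 = 0.7
        w.oxic = False
        budget = reduce_step(w, r)
        assert budget.np_reduced == pytest.approx(70.0)


class TestBioticOxidation:
    def test_empty_dissolved_pool_is_a_noop(self):
        w = make_world(initial_number_fe2oxidizer=0)
        add_agent(w, "oxidizer", (1, 1, 1))
        w.oxic = True
        assert biotic_oxidation_step(w) == 0.0
        assert w.nps.count == 0

    def test_shedding_seeds_forty_equal_particles(self):
        w = make_world(start_medium_fe2=3600.0, contact_oxidation_rate=3600.0)
        add_agent(w, "oxidizer", (1, 1, 1))
        w.oxic = True
        used = biotic_oxidation_step(w)
        assert used == pytest.approx(3600.0)
        o = w.oxidizers[0]
        assert len(o.surface_nps) == 40
        assert np.allclose(w.nps.fe3[np.asarray(o.surface_nps)], 90.0)
        assert w.dissolved_fe2 == pytest.approx(0.0)

    def test_shedding_remainder_grows_existing_particles_by_area_share(self):
        w = make_world(start_medium_fe2=4000.0, contact_oxidation_rate=4000.0)
        add_agent(w, "oxidizer", (1, 1, 1))
        o = w.oxidizers[0]
        # pre-existing surface: 30 particles -> 10 new seeds, 3/4 as remainder
        for _ in range(30):
            i = w.nps.add(fe3=100.0, fe2=0.0, pos=o.position.copy(),
                          heading=random_unit_vectors(w.rng, 1)[0],
                          bound_kind=2, host=0)
            o.surface_nps.append(i)
        w.oxic = True
        used = biotic_oxidation_step(w)
        assert used == pytest.approx(4000.0)
        assert len(o.surface_nps) == 40
        total_np_iron = w.nps.iron_sum()
        assert total_np_iron == pytest.approx(30 * 100.0 + 4000.0)

    def test_low_ph_mode_creates_free_particle_when_none_nearby(self):
        w = make_world(start_medium_fe2=500.0, encrustation_mode="low_ph")
        add_agent(w, "oxidizer", (3, 3, 3))
        w.oxic = True
        used = biotic_oxidation_step(w)
        idx = w.nps.indices()
        assert len(idx) == 1
        assert w.nps.bound_kind[idx[0]] == 0  # free from the start
        assert w.nps.fe3[idx[0]] == pytest.approx(used)

    def test_low_ph_mode_feeds_neighbourhood_particles_equally(self):
        w = make_world(start_medium_fe2=900.0, encrustation_mode="low_ph",
                       contact_oxidation_rate=900.0)
        add_agent(w, "oxidizer", (3, 3, 3))
        a = w.nps.add(fe3=10.0, fe2=0.0, pos=np.array([3.5, 3.5, 3.5]),
                      heading=np.array([1.0, 0, 0]))
        b = w.nps.add(fe3=10.0, fe2=0.0, pos=np.array([4.5, 3.5, 3.5]),
                      heading=np.array([1.0, 0, 0]))
        w.oxic = True
        biotic_oxidation_step(w)
        assert w.nps.count == 2
        assert w.nps.fe3[a] == pytest.approx(10.0 + 450.0)
        assert w.nps.fe3[b] == pytest.approx(10.0 + 450.0)

    def test_gated_to_oxic(self):
        w = make_world()
        w.oxic = False
        with pytest.raises(ValueError):
            biotic_oxidation_step(w)


class TestAbioticOxidation:
    def test_first_order_rule_on_dissolved_pool(self):
        w = make_world(start_medium_fe2=1e4, abiotic_oxidation_ratio=0.01,
                       fe_patch_percentage=10.0)
        w.oxic = True
        total_before = w.iron_total()
        oxidized = abiotic_oxidation_step(w)
        assert oxidized == pytest.approx(100.0)
        assert w.dissolved_fe2 == pytest.approx(9900.0)
        assert w.iron_total() == pytest.approx(total_before)

    def test_zero_ratio_changes_nothing(self):
        w = make_world(start_medium_fe2=1e4, abiotic_oxidation_ratio=0.0)
        w.oxic = True
        assert abiotic_oxidation_step(w) == 0.0
        assert w.dissolved_fe2 == 1e4

    def test_particle_fe2_oxidises_in_place_conserving_content(self):
        w = make_world(abiotic_oxidation_ratio=0.01, fe_patch_percentage=10.0)
        i = w.nps.add(fe3=0.0, fe2=1000.0, pos=np.array([1.5, 1.5, 1.5]),
                      heading=np.array([1.0, 0, 0]))
        w.oxic = True
        abiotic_oxidation_step(w)
        assert w.nps.fe2[i] == pytest.approx(990.0)
        assert w.nps.fe3[i] == pytest.approx(10.0)
        assert w.nps.total_iron(i) == pytest.approx(1000.0)

    def test_dissolved_share_without_bulk_becomes_a_free_particle(self):
        w = make_world(start_medium_fe2=1000.0, abiotic_oxidation_ratio=0.1)
        w.oxic = True
        abiotic_oxidation_step(w)
        assert w.nps.count == 1
        i = w.nps.indices()[0]
        assert w.nps.fe3[i] == pytest.approx(100.0)
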