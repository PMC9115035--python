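"""Phase exchange: nanoparticle dissociation, Fe2+ equilibration between
solids and solution, stochastic particle loss, and the secondary-mineral
aging clock."""

from __future__ import annotations

import numpy as np

from .agents import BOUND_OXIDIZER, BOUND_REDUCER, FREE, random_unit_vectors
from .world import World


# ----------------------------------------------------------------------
# scalar rule functions (the engine applies their vectorised equivalents)
def dissociate_from_reducer(fe2_fraction: float, threshold: float) -> bool:
    """Surface passivation: a bound particle is released once its Fe2+ share
    exceeds the dissociation threshold (strict)."""
    return fe2_fraction > threshold


def dissociate_from_oxidizer(diameter: float, shedding_diameter: float,
                             rng: np.random.Generator, sd: float = 2.0) -> bool:
    """Stochastic shedding: a draw from Normal(diameter, sd) exceeding the
    shedding diameter releases the particle."""
    return rng.normal(diameter, sd) > shedding_diameter


# ----------------------------------------------------------------------
def dissociation_step(world: World) -> None:
    cfg = world.cfg
    nps = world.nps

    bound_r = nps.indices(kind=BOUND_REDUCER)
    if len(bound_r) > 0:
        frac2 = nps.fe2[bound_r] / nps.total_iron(bound_r)
        freed = bound_r[frac2 > cfg.np_dissociation_threshold]
        if len(freed) > 0:
            _release(world, freed)

    bound_o = nps.indices(kind=BOUND_OXIDIZER)
    if len(bound_o) > 0:
        d = nps.diameters(bound_o, cfg.iron_per_cubicnm, cfg.unit_scale)
        draw = world.rng.normal(d, cfg.shedding_sd)
        shed = draw > cfg.shedding_diameter
        freed = bound_o[shed]
        if len(freed) > 0:
            world.shed_diameter_sum += float(d[shed].sum())
            world.shed_count += int(shed.sum())
            _release(world, freed)


def _release(world: World, idx: np.ndarray) -> None:
    nps = world.nps
    hosts_r = [world.reducers[h].bound_nps
               for h in np.unique(nps.host[idx][nps.bound_kind[idx] == BOUND_REDUCER])]
    hosts_o = [world.oxidizers[h].surface_nps
               for h in np.unique(nps.host[idx][nps.bound_kind[idx] == BOUND_OXIDIZER])]
    freed = set(int(i) for i in idx)
    for lst in hosts_r + hosts_o:
        lst[:] = [i for i in lst if i not in freed]
    nps.bound_kind[idx] = FREE
    nps.host[idx] = -1
    nps.heading[idx] = random_unit_vectors(world.rng, len(idx))


# ----------------------------------------------------------------------
def equilibrate(world: World) -> None:
    """Move Fe2+ between solid surfaces and solution toward the adsorption
    equilibrium.

    Every solid entity (bulk patch or nanoparticle) has local target
    ``A* = fe2_solid_ineq * (A + D/N)`` where D is the dissolved pool and N the
    number of solid entities; a fraction ``fe2_equilibrium_rate`` of the
    deviation is transferred per tick, direction depending on the sign.  Bulk
    patches equilibrate first, then nanoparticles; draws from solution are
    scaled down proportionally if they would overdraw the pool."""
    cfg = world.cfg
    nps = world.nps
    bulk = world.bulk_coords
    alive = nps.indices()
    n_solid = len(bulk) + len(alive)
    if n_solid == 0:
        return

    def stage(amounts: np.ndarray) -> np.ndarray:
        d_share = world.dissolved_fe2 / n_solid
        target = cfg.fe2_solid_ineq * (amounts + d_share)
        delta = cfg.fe2_equilibrium_rate * (amounts - target)
        release = np.clip(delta, 0.0, None)
        draw = np.clip(-delta, 0.0, None)
        world.dissolved_fe2 += float(release.sum())
        amounts = amounts - release
        total_draw = float(draw.sum())
        if total_draw > 0:
            scale = min(1.0, world.dissolved_fe2 / total_draw)
            amounts = amounts + draw * scale
            world.dissolved_fe2 -= total_draw * scale
        return amounts

    if len(bulk) > 0:
        sel = (bulk[:, 0], bulk[:, 1], bulk[:, 2])
        world.fe2_ads[sel] = stage(world.fe2_ads[sel])
    if len(alive) > 0:
        nps.fe2[alive] = stage(nps.fe2[alive])


# ----------------------------------------------------------------------
def np_loss(world: World) -> int:
    """Each free nanoparticle leaves the system (sedimentation, burial in bulk
    mineral, ...) with probability np_loss_percentage/100 per tick; its iron
    moves to the removal ledger so the global balance stays closed."""
    p = world.cfg.np_loss_percentage / 100.0
    if p <= 0:
        return 0
    nps = world.nps
    free = nps.indices(kind=FREE)
    if len(free) == 0:
        return 0
    gone = free[world.rng.random(len(free)) < p]
    for i in gone:
        world.removed_iron += float(nps.fe3[i] + nps.fe2[i])
        nps.remove(int(i))
    return len(gone)


def aging_step(world: World) -> None:
    """Advance the per-particle 'minutes since last reduction' clock.  The
    clock always runs; it only affects reduction when aging is enabled (see
    :func:`ironcycle.redox.susceptibility`)."""
    idx = world.nps.indices()
    if len(idx) > 0:
        world.nps.clock[idx] += 1


def update_aging(clock: int, aging_lag: int, aging_rate: float) -> float:
    """Susceptibility for a particle not reduced for ``clock`` minutes."""
    return float(np.clip(1.0 - aging_rate * max(0, clock - aging_lag), 0.0, 1.0))
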