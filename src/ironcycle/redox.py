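"""Redox submodels.

Anoxic ticks: each reducer performs contact reduction of the bulk patch it is
attached to, then spends a shared "reduction capacity" of four times the
contact rate — the MtrC/electron-shuttle budget — first on bound nanoparticles
and then, spread equally, on bulk patches within the electron-shuttle range.
With no bound nanoparticles this reproduces the observed 80:20 split of
shuttle-mediated versus contact reduction.

Oxic ticks: each oxidizer converts dissolved Fe2+ into particulate Fe3+
(growing surface nanoparticles in shedding mode, or feeding free particles in
the low-pH mode), after which every Fe2+ pool loses a first-order share to
abiotic oxidation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agents import BOUND_OXIDIZER, Reducer, random_unit_vectors
from .world import MOORE_OFFSETS, World


def mtrc_occupancy(diameter: float, cell_surface_area: float,
                   total_mtrc: int = 10_000) -> tuple:
    """MtrC proteins occupied by one bound nanoparticle and the occupied
    fraction: occupied = d^2 / area * total, fraction = d^2 / area."""
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    fraction = diameter**2 / cell_surface_area
    return fraction * total_mtrc, fraction


@dataclass
class ReductionBudget:
    """Accounting of one reducer's reduction tick (iron units)."""

    contact_reduced: float = 0.0
    np_reduced: float = 0.0
    shuttle_reduced: float = 0.0
    capacity_initial: float = 0.0

    @property
    def total(self) -> float:
        return self.contact_reduced + self.np_reduced + self.shuttle_reduced


def susceptibility(world: World, idx) -> np.ndarray:
    """Reduction susceptibility of nanoparticles under secondary-mineral aging:
    1 until ``aging_lag`` minutes without reduction, then linear decay at
    ``aging_rate`` per minute, clamped to [0, 1]."""
    cfg = world.cfg
    if not cfg.aging_enabled:
        return np.ones(np.shape(idx), dtype=float)
    over = np.maximum(0, world.nps.clock[idx] - cfg.aging_lag)
    return np.clip(1.0 - cfg.aging_rate * over, 0.0, 1.0)


def reduce_step(world: World, reducer: Reducer) -> ReductionBudget:
    """One anoxic reduction tick for a single reducer."""
    if world.oxic:
        raise ValueError("reduction only runs under anoxic conditions")
    cfg = world.cfg
    nps = world.nps
    budget = ReductionBudget(capacity_initial=4.0 * cfg.contact_reduction_rate)

    # (1) contact reduction of the attached patch
    if reducer.attached:
        patch = reducer.attached_patch
        x = min(cfg.contact_reduction_rate, float(world.fe3[patch]))
        if x > 0:
            world.fe3[patch] -= x
            world.fe2_ads[patch] += x
            budget.contact_reduced = x

    # (2) bound nanoparticles draw on the shared MtrC capacity, visited in
    # random order; each transfer of x iron units charges x/ratio capacity
    capacity = budget.capacity_initial
    ratio = cfg.np_mineral_reduction_ratio
    if reducer.bound_nps and capacity > 0:
        idx = np.asarray(reducer.bound_nps)
        idx = idx[world.rng.permutation(len(idx))]
        fe3v = nps.fe3[idx]
        has = fe3v > 0
        if has.any():
            idx, fe3v = idx[has], fe3v[has]
            d = nps.diameters(idx, cfg.iron_per_cubicnm, cfg.unit_scale)
            frac = np.minimum(d**2 / cfg.cell_surface_area, 1.0)
            want = (frac * ratio * cfg.contact_reduction_rate
                    * susceptibility(world, idx))
            x = np.minimum(want, fe3v)
            charge = x / ratio
            cum = np.cumsum(charge)
            allowed = np.minimum(charge, np.maximum(capacity - (cum - charge), 0.0))
            x = allowed * ratio
            nps.fe3[idx] -= x
            nps.fe2[idx] += x
            nps.clock[idx[x > 0]] = 0
            capacity -= float(allowed.sum())
            budget.np_reduced = float(x.sum())

    # (3) remaining capacity goes out as electron shuttles, split equally over
    # bulk patches in range, each transfer capped by the patch's Fe3+
    if capacity > 0:
        sel = world.shuttle_patches(world.patch_of(reducer.position))
        if len(sel[0]) > 0:
            share = capacity / len(sel[0])
            amounts = np.minimum(share, world.fe3[sel])
            world.fe3[sel] -= amounts
            world.fe2_ads[sel] += amounts
            budget.shuttle_reduced = float(amounts.sum())

    world.cum_reduced += budget.total
    world.cum_np_reduced += budget.np_reduced
    return budget


def reduction_step(world: World) -> None:
    for i in world.rng.permutation(len(world.reducers)):
        reduce_step(world, world.reducers[i])


# ----------------------------------------------------------------------
def biotic_oxidation_step(world: World) -> float:
    """All oxidizers take their turn (random order); returns total Fe2+ used.

    Each draws min(dissolved/n, contact_oxidation_rate) from the dissolved pool
    and precipitates it as nanoparticle Fe3+ according to the encrustation
    mode."""
    if not world.oxic:
        raise ValueError("biotic oxidation only runs under oxic conditions")
    cfg = world.cfg
    n_ox = len(world.oxidizers)
    if n_ox == 0:
        return 0.0
    share = world.dissolved_fe2 / n_ox
    total_used = 0.0
    for i in world.rng.permutation(n_ox):
        o = world.oxidizers[i]
        fe2_used = min(share, cfg.contact_oxidation_rate, world.dissolved_fe2)
        if fe2_used <= 0:
            continue
        world.dissolved_fe2 -= fe2_used
        world.cum_biotic_ox += fe2_used
        total_used += fe2_used
        if cfg.encrustation_mode == "shedding":
            _shedding_precipitate(world, int(i), fe2_used)
        else:
            _low_ph_precipitate(world, o, fe2_used)
    return total_used


def _shedding_precipitate(world: World, ox_idx: int, fe2_used: float) -> None:
    """Top the oxidizer's surface up to 40 nanoparticles, seeding each new one
    with fe2_used/40; the remainder grows existing surface particles in
    proportion to their squared diameter (surface-area share)."""
    cfg = world.cfg
    nps = world.nps
    o = world.oxidizers[ox_idx]
    n_new = max(0, 40 - len(o.surface_nps))
    seed = fe2_used / 40.0
    spent = 0.0
    if n_new > 0 and seed > 0:
        for _ in range(n_new):
            i = nps.add(
                fe3=seed, fe2=0.0, pos=o.position.copy(),
                heading=random_unit_vectors(world.rng, 1)[0],
                bound_kind=BOUND_OXIDIZER, host=ox_idx,
            )
            o.surface_nps.append(i)
        spent = n_new * seed
    remainder = fe2_used - spent
    if remainder > 0:
        if o.surface_nps:
            idx = np.asarray(o.surface_nps)
            d2 = nps.diameters(idx, cfg.iron_per_cubicnm, cfg.unit_scale) ** 2
            nps.fe3[idx] += remainder * d2 / d2.sum()
        else:  # no surface particle could be seeded (fe2_used was ~0): free NP
            nps.add(fe3=remainder, fe2=0.0, pos=o.position.copy(),
                    heading=random_unit_vectors(world.rng, 1)[0])


def _low_ph_precipitate(world: World, oxidizer, fe2_used: float) -> None:
    """Low-pH mode: Fe3+ precipitates onto nanoparticles in the 27-patch
    neighbourhood, or nucleates one new free particle if none are present."""
    nps = world.nps
    alive = nps.indices()
    if len(alive) > 0:
        patch = world.patch_of(oxidizer.position)
        nbhd = (patch + np.vstack([[0, 0, 0], MOORE_OFFSETS])) % world.g
        nbhd_lin = np.unique(world.lin(nbhd))
        np_lin = world.lin(world.patch_of(nps.pos[alive]))
        near = alive[np.isin(np_lin, nbhd_lin)]
    else:
        near = alive
    if len(near) == 0:
        nps.add(fe3=fe2_used, fe2=0.0, pos=oxidizer.position.copy(),
                heading=random_unit_vectors(world.rng, 1)[0])
    else:
        nps.fe3[near] += fe2_used / len(near)


def abiotic_oxidation_step(world: World) -> float:
    """First-order abiotic oxidation: each Fe2+ pool loses the
    ``abiotic_oxidation_ratio`` share per tick.  Adsorbed and particle Fe2+
    oxidise in place; the dissolved share precipitates as Fe3+ spread equally
    over the bulk cluster edge patches (or one new free particle if the world
    holds no bulk mineral)."""
    if not world.oxic:
        raise ValueError("abiotic oxidation only runs under oxic conditions")
    r = world.cfg.abiotic_oxidation_ratio
    if r <= 0:
        return 0.0
    nps = world.nps

    a_ads = r * world.fe2_ads
    world.fe2_ads -= a_ads
    world.fe3 += a_ads
    total = float(a_ads.sum())

    alive = nps.indices()
    if len(alive) > 0:
        a_np = r * nps.fe2[alive]
        nps.fe2[alive] -= a_np
        nps.fe3[alive] += a_np
        total += float(a_np.sum())

    a_dis = r * world.dissolved_fe2
    if a_dis > 0:
        world.dissolved_fe2 -= a_dis
        edges = world.edge_coords
        if len(edges) > 0:
            world.fe3[edges[:, 0], edges[:, 1], edges[:, 2]] += a_dis / len(edges)
        else:
            nps.add(fe3=a_dis, fe2=0.0, pos=world.random_medium_position(),
                    heading=random_unit_vectors(world.rng, 1)[0])
        total += a_dis

    world.cum_abiotic_ox += total
    return total
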