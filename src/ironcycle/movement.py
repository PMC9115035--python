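"""Movement and adhesion: diffusive nanoparticles/oxidizers, run-and-tumble
chemotaxis of reducers, contact aggregation/binding, and mineral
attachment/detachment under the electrostatic and biofilm modes.

Agents advance in straight jumps of ``speed`` patch lengths per tick, with a
random reorientation ("tumble") beforehand with some probability.  Reducers in
chemotactic mode (recent bulk-mineral contact) tumble three times as often and
move twice as fast.
"""

from __future__ import annotations

import numpy as np

from .agents import (
    FREE,
    BOUND_REDUCER,
    Reducer,
    fe3_fraction,
    np_speed,
    random_unit_vectors,
)
from .world import World


# ----------------------------------------------------------------------
# primitives
def redirect_to_cluster_edge(world: World, cluster_id: int, from_position) -> tuple:
    """Edge patch of the given cluster closest (wrapped Euclidean) to the
    position; ties broken with the world RNG."""
    edges = world.cluster_edges.get(int(cluster_id))
    if edges is None or len(edges) == 0:
        raise ValueError(f"cluster {cluster_id} has no edge patches")
    d = world.wrapped_distance(edges + 0.5, np.asarray(from_position, dtype=float))
    best = np.flatnonzero(d == d.min())
    pick = best[world.rng.integers(len(best))] if len(best) > 1 else best[0]
    return tuple(int(v) for v in edges[pick])


def _apply_core_redirect(world: World, pos: np.ndarray) -> np.ndarray:
    """If a continuous position sits inside a non-traversable bulk-core patch,
    move it to the nearest edge patch of that cluster (patch centre)."""
    patch = world.patch_of(pos)
    if world.is_core[tuple(patch)]:
        cid = int(world.cluster_id[tuple(patch)])
        edge = redirect_to_cluster_edge(world, cid, pos)
        return np.asarray(edge, dtype=float) + 0.5
    return pos


def try_mineral_adhesion(world: World, reducer: Reducer) -> bool:
    """Attach iff the reducer stands on a bulk patch whose adsorbed Fe2+ is
    strictly below fe2_ads_tolerance."""
    patch = tuple(world.patch_of(reducer.position))
    if not world.is_bulk[patch]:
        return False
    if world.fe2_ads[patch] < world.cfg.fe2_ads_tolerance:
        reducer.attached_patch = patch
        reducer.ticks_attached = 0
        return True
    return False


def _n_coclustered(world: World, reducer: Reducer) -> int:
    """Other reducers attached to the same cluster within 2 patch lengths."""
    cid = world.cluster_id[reducer.attached_patch]
    n = 0
    for other in world.reducers:
        if other is reducer or not other.attached:
            continue
        if world.cluster_id[other.attached_patch] != cid:
            continue
        if world.wrapped_distance(other.position, reducer.position) <= 2.0:
            n += 1
    return n


def maybe_detach(world: World, reducer: Reducer) -> bool:
    """Detachment check for an attached reducer; returns True if it let go."""
    cfg = world.cfg
    patch = reducer.attached_patch
    if world.fe2_ads[patch] > cfg.fe2_ads_tolerance:
        if cfg.adhesion_mode == "electrostatic":
            detach = True
        else:  # biofilm: probability decays with residence time, is damped by
            # neighbours on the cluster and is raised under oxic conditions
            p = (
                cfg.detach_p0
                * 2.0 ** (-reducer.ticks_attached / cfg.detach_tau)
                / (1.0 + _n_coclustered(world, reducer))
            )
            if world.oxic:
                p *= cfg.detach_oxic_multiplier
            detach = world.rng.random() < min(p, 1.0)
        if detach:
            reducer.attached_patch = None
            reducer.ticks_attached = 0
            reducer.heading = random_unit_vectors(world.rng, 1)[0]
            return True
    reducer.ticks_attached += 1
    return False


def _mtrc_load(world: World, reducer: Reducer) -> float:
    """Summed MtrC occupancy fraction (d^2 / cell surface area) of bound NPs."""
    if not reducer.bound_nps:
        return 0.0
    cfg = world.cfg
    d = world.nps.diameters(
        np.asarray(reducer.bound_nps), cfg.iron_per_cubicnm, cfg.unit_scale
    )
    return float(np.sum(d**2) / cfg.cell_surface_area)


def _try_bind(world: World, np_idx: int, r_idx: int) -> bool:
    """Bind a free nanoparticle to a reducer if its Fe3+ share exceeds the
    attachment threshold and the cell's MtrC occupancy stays <= 1."""
    cfg = world.cfg
    nps = world.nps
    frac = fe3_fraction(nps.fe3[np_idx], nps.fe2[np_idx])
    if frac <= cfg.np_attachment_threshold / 100.0:
        return False
    reducer = world.reducers[r_idx]
    d = nps.diameters(np_idx, cfg.iron_per_cubicnm, cfg.unit_scale)
    if _mtrc_load(world, reducer) + float(d) ** 2 / cfg.cell_surface_area > 1.0:
        return False
    nps.bound_kind[np_idx] = BOUND_REDUCER
    nps.host[np_idx] = r_idx
    nps.pos[np_idx] = reducer.position
    reducer.bound_nps.append(int(np_idx))
    return True


def _merge(world: World, keep: int, absorb: int) -> None:
    """Aggregate two free nanoparticles, conserving iron; the merged particle
    keeps the iron-weighted mean of the two aging clocks."""
    nps = world.nps
    wa = nps.fe3[keep] + nps.fe2[keep]
    wb = nps.fe3[absorb] + nps.fe2[absorb]
    nps.clock[keep] = int(round((nps.clock[keep] * wa + nps.clock[absorb] * wb) / (wa + wb)))
    nps.fe3[keep] += nps.fe3[absorb]
    nps.fe2[keep] += nps.fe2[absorb]
    nps.remove(absorb)


# ----------------------------------------------------------------------
# aggregate-adhere contact pass
def aggregate_adhere(world: World, mover_idx: np.ndarray) -> None:
    """Contact rules after movement: each just-moved free nanoparticle calls the
    other free nanoparticles and reducers on its patch in random order, merging
    with probability mineral_aggregation_probability/100 or binding to a
    reducer; processing of a mover stops at its first merge or bind."""
    if len(mover_idx) == 0:
        return
    nps = world.nps
    rng = world.rng
    p_merge = world.cfg.mineral_aggregation_probability / 100.0

    np_lin = world.lin(world.patch_of(nps.pos[mover_idx]))
    reducer_lin: dict[int, list[int]] = {}
    for ri, r in enumerate(world.reducers):
        reducer_lin.setdefault(int(world.lin(world.patch_of(r.position))), []).append(ri)

    order = np.argsort(np_lin, kind="stable")
    sorted_lin = np_lin[order]
    boundaries = [0, *(np.flatnonzero(np.diff(sorted_lin)) + 1), len(order)]

    for b0, b1 in zip(boundaries, boundaries[1:]):
        grp = order[b0:b1]
        lin = int(sorted_lin[b0])
        rs = reducer_lin.get(lin, [])
        if len(grp) < 2 and not rs:
            continue
        members = [int(mover_idx[j]) for j in grp]
        if not rs and p_merge >= 1.0 and len(members) > 1:
            # certain aggregation with no reducer present: the whole group
            # collapses into one particle regardless of call order
            keep, rest = members[0], members[1:]
            w_all = nps.total_iron(np.asarray(members))
            nps.clock[keep] = int(round(
                float(np.dot(nps.clock[np.asarray(members)], w_all)) / w_all.sum()
            ))
            nps.fe3[keep] += float(nps.fe3[rest].sum())
            nps.fe2[keep] += float(nps.fe2[rest].sum())
            for other in rest:
                nps.remove(other)
            continue
        for i in rng.permutation(len(members)):
            me = members[i]
            if not nps.alive[me] or nps.bound_kind[me] != FREE:
                continue
            candidates = [("np", j) for j in members if j != me
                          and nps.alive[j] and nps.bound_kind[j] == FREE]
            candidates += [("red", ri) for ri in rs]
            if not candidates:
                continue
            for k in rng.permutation(len(candidates)):
                kind, who = candidates[k]
                if kind == "np":
                    if not nps.alive[who] or nps.bound_kind[who] != FREE:
                        continue
                    if rng.random() < p_merge:
                        _merge(world, me, who)
                        break
                else:
                    if _try_bind(world, me, who):
                        break


# ----------------------------------------------------------------------
# per-tick movement phases
def _move_free_nps(world: World) -> None:
    cfg = world.cfg
    nps = world.nps
    idx = nps.indices(kind=FREE)
    if len(idx) == 0:
        return
    rng = world.rng
    tumble = rng.random(len(idx)) < cfg.tumble_probability
    if tumble.any():
        nps.heading[idx[tumble]] = random_unit_vectors(rng, int(tumble.sum()))
    speed = np_speed(nps.diameters(idx, cfg.iron_per_cubicnm, cfg.unit_scale))
    nps.pos[idx] = (nps.pos[idx] + nps.heading[idx] * speed[:, None]) % world.g

    # redirect any particle that landed inside a bulk-core patch
    patch = world.patch_of(nps.pos[idx])
    core = world.is_core[patch[:, 0], patch[:, 1], patch[:, 2]]
    for j in np.flatnonzero(core):
        nps.pos[idx[j]] = _apply_core_redirect(world, nps.pos[idx[j]])

    aggregate_adhere(world, idx)


def diffuse_move(world: World, position, heading, speed: float):
    """One diffusive step for a bacterium: tumble, jump, core-redirect.
    Returns (position, heading)."""
    rng = world.rng
    if rng.random() < world.cfg.tumble_probability:
        heading = random_unit_vectors(rng, 1)[0]
    position = (position + heading * speed) % world.g
    position = _apply_core_redirect(world, position)
    return position, heading


def _move_oxidizers(world: World) -> None:
    for i in world.rng.permutation(len(world.oxidizers)):
        o = world.oxidizers[i]
        o.position, o.heading = diffuse_move(
            world, o.position, o.heading, world.cfg.speed_fe2_oxidizer
        )


def chemotactic_move(world: World, reducer: Reducer) -> None:
    """Run-and-tumble step with mineral-contact memory: any bulk neighbour
    resets the persistence timer; while it runs, tumbling is tripled and speed
    doubled.  Afterwards the reducer may capture co-located nanoparticles and
    attempt mineral adhesion."""
    cfg = world.cfg
    rng = world.rng
    patch = tuple(world.patch_of(reducer.position))
    if world.has_bulk_neighbor[patch] or world.is_bulk[patch]:
        reducer.chemotactic_timer = cfg.chemo_persistence
    if reducer.chemotactic_timer > 0:
        p_tumble = 3.0 * cfg.tumble_probability
        speed = 2.0 * cfg.speed_fe3_reducer
        reducer.chemotactic_timer -= 1
    else:
        p_tumble = cfg.tumble_probability
        speed = cfg.speed_fe3_reducer
    if rng.random() < p_tumble:
        reducer.heading = random_unit_vectors(rng, 1)[0]
    reducer.position = (reducer.position + reducer.heading * speed) % world.g
    reducer.position = _apply_core_redirect(world, reducer.position)


def _reducer_capture_nps(world: World, r_idx: int, free_by_patch: dict) -> None:
    """A moved reducer calls the free nanoparticles on its patch and binds
    every qualifying one (MtrC occupancy permitting)."""
    nps = world.nps
    r = world.reducers[r_idx]
    lin_r = int(world.lin(world.patch_of(r.position)))
    here = free_by_patch.get(lin_r)
    if not here:
        return
    for j in world.rng.permutation(len(here)):
        i = here[j]
        if nps.alive[i] and nps.bound_kind[i] == FREE:
            _try_bind(world, int(i), r_idx)


def _move_reducers(world: World) -> None:
    nps = world.nps
    free = nps.indices(kind=FREE)
    free_by_patch: dict[int, list] = {}
    if len(free) > 0:
        for lin, i in zip(world.lin(world.patch_of(nps.pos[free])), free):
            free_by_patch.setdefault(int(lin), []).append(int(i))
    for i in world.rng.permutation(len(world.reducers)):
        r = world.reducers[i]
        if r.attached:
            maybe_detach(world, r)
            continue
        chemotactic_move(world, r)
        _reducer_capture_nps(world, int(i), free_by_patch)
        try_mineral_adhesion(world, r)


def _carry_bound_nps(world: World) -> None:
    """Bound nanoparticles ride on their host's position."""
    nps = world.nps
    for ri, r in enumerate(world.reducers):
        if r.bound_nps:
            nps.pos[np.asarray(r.bound_nps)] = r.position
    for oi, o in enumerate(world.oxidizers):
        if o.surface_nps:
            nps.pos[np.asarray(o.surface_nps)] = o.position


def movement_step(world: World) -> None:
    """Movement submodel: free nanoparticles, then oxidizers, then reducers."""
    _move_free_nps(world)
    _move_oxidizers(world)
    _move_reducers(world)
    _carry_bound_nps(world)
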