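"""The 3-D toroidal lattice world and the per-tick submodel loop.

Patches are stored as dense arrays over the ``(g, g, g)`` grid: a boolean bulk
mask, Fe3+ reservoirs, adsorbed Fe2+ and cluster ids.  Dissolved Fe2+ is a
single well-mixed pool (the model operates at a time scale where dissolved
Fe2+ mixes completely within one tick).  Topology is toroidal with a 26-cell
Moore neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agents import (
    NanoparticleStore,
    Oxidizer,
    Reducer,
    np_iron_from_diameter,
    random_unit_vectors,
)
from .config import WorldConfig
from .schedule import OXIC, OxicSchedule

MOORE_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.int64,
)


@dataclass(frozen=True)
class Patch:
    """Read-only view of one lattice cell."""

    coords: tuple
    kind: str          # "medium" | "bulk"
    fe3: float
    fe2_ads: float
    cluster_id: int | None
    is_edge: bool | None


class World:
    """Simulation state: lattice, pools, agent registries and counters."""

    def __init__(self, config: WorldConfig, seed: int):
        self.cfg = config
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        g = config.grid_side
        self.g = g

        self.is_bulk = np.zeros((g, g, g), dtype=bool)
        self.fe3 = np.zeros((g, g, g))
        self.fe2_ads = np.zeros((g, g, g))
        self.cluster_id = np.full((g, g, g), -1, dtype=np.int32)

        self.dissolved_fe2 = float(config.start_medium_fe2)
        self.removed_iron = 0.0
        self.tick = 0
        self.oxic = False

        self.nps = NanoparticleStore()
        self.reducers: list[Reducer] = []
        self.oxidizers: list[Oxidizer] = []

        # cumulative counters (iron units)
        self.cum_reduced = 0.0
        self.cum_np_reduced = 0.0
        self.cum_biotic_ox = 0.0
        self.cum_abiotic_ox = 0.0
        # shed-diameter statistics (nm)
        self.shed_diameter_sum = 0.0
        self.shed_count = 0

        # filled by _finalise_lattice()
        self.is_core = np.zeros((g, g, g), dtype=bool)
        self.is_edge = np.zeros((g, g, g), dtype=bool)
        self.has_bulk_neighbor = np.zeros((g, g, g), dtype=bool)
        self.cluster_edges: dict[int, np.ndarray] = {}
        self.bulk_coords = np.zeros((0, 3), dtype=np.int64)
        self.edge_coords = np.zeros((0, 3), dtype=np.int64)
        self._shuttle_cache: dict[int, tuple] = {}

    # ------------------------------------------------------------------
    # geometry helpers
    def lin(self, coords: np.ndarray) -> np.ndarray:
        """Linear index of integer patch coordinates (array of shape (..., 3))."""
        coords = np.asarray(coords)
        g = self.g
        return (coords[..., 0] * g + coords[..., 1]) * g + coords[..., 2]

    def patch_of(self, position: np.ndarray) -> np.ndarray:
        """Integer patch coordinates of continuous position(s)."""
        return np.floor(np.asarray(position)).astype(np.int64) % self.g

    def wrapped_delta(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        g = self.g
        return (np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + g / 2.0) % g - g / 2.0

    def wrapped_distance(self, a, b) -> np.ndarray:
        return np.linalg.norm(self.wrapped_delta(a, b), axis=-1)

    def patch_at(self, coords) -> Patch:
        c = tuple(int(v) % self.g for v in coords)
        bulk = bool(self.is_bulk[c])
        return Patch(
            coords=c,
            kind="bulk" if bulk else "medium",
            fe3=float(self.fe3[c]),
            fe2_ads=float(self.fe2_ads[c]),
            cluster_id=int(self.cluster_id[c]) if bulk else None,
            is_edge=bool(self.is_edge[c]) if bulk else None,
        )

    @property
    def n_patches(self) -> int:
        return self.g**3

    # ------------------------------------------------------------------
    def _finalise_lattice(self) -> None:
        """Derive core/edge masks and per-cluster edge lists (bulk is static)."""
        all_bulk_neighbors = np.ones_like(self.is_bulk)
        any_bulk_neighbor = np.zeros_like(self.is_bulk)
        for off in MOORE_OFFSETS:
            rolled = np.roll(self.is_bulk, shift=tuple(-off), axis=(0, 1, 2))
            all_bulk_neighbors &= rolled
            any_bulk_neighbor |= rolled
        self.is_core = self.is_bulk & all_bulk_neighbors
        self.is_edge = self.is_bulk & ~all_bulk_neighbors
        self.has_bulk_neighbor = any_bulk_neighbor
        self.bulk_coords = np.argwhere(self.is_bulk)
        self.edge_coords = np.argwhere(self.is_edge)
        self.cluster_edges = {}
        for c in np.unique(self.cluster_id[self.cluster_id >= 0]):
            coords = np.argwhere((self.cluster_id == c) & self.is_edge)
            self.cluster_edges[int(c)] = coords
        self._shuttle_cache = {}

    def shuttle_patches(self, patch_coords) -> tuple:
        """Bulk patches whose centres lie within e_shuttle_range of the given
        patch centre.  Returns (coords_tuple_arrays,) for fancy indexing."""
        key = int(self.lin(np.asarray(patch_coords)))
        hit = self._shuttle_cache.get(key)
        if hit is None:
            if len(self.bulk_coords) == 0:
                hit = (np.zeros(0, np.int64),) * 3
            else:
                d = self.wrapped_distance(self.bulk_coords, np.asarray(patch_coords))
                sel = self.bulk_coords[d <= self.cfg.e_shuttle_range]
                hit = (sel[:, 0], sel[:, 1], sel[:, 2])
            self._shuttle_cache[key] = hit
        return hit

    # ------------------------------------------------------------------
    def iron_total(self) -> float:
        """Total iron over every pool plus the removal ledger (conserved)."""
        return (
            self.dissolved_fe2
            + float(self.fe2_ads.sum())
            + float(self.fe3.sum())
            + self.nps.iron_sum()
            + self.removed_iron
        )

    def random_medium_position(self) -> np.ndarray:
        medium = np.argwhere(~self.is_bulk)
        if len(medium) == 0:
            raise ValueError("world has no medium patches")
        i = self.rng.integers(len(medium))
        return medium[i] + self.rng.random(3)


# ----------------------------------------------------------------------
def _place_bulk_clusters(world: World, n_bulk: int) -> None:
    """Clustered growth: seed count max(1, round(n_bulk*(1-fe_clustering))),
    then repeatedly convert a uniformly chosen medium neighbour of the
    existing bulk set until n_bulk patches are bulk."""
    if n_bulk <= 0:
        return
    cfg, rng, g = world.cfg, world.rng, world.g
    n_seeds = min(n_bulk, max(1, round(n_bulk * (1.0 - cfg.fe_clustering))))
    flat_choice = rng.choice(g**3, size=n_seeds, replace=False)
    seeds = np.stack(np.unravel_index(flat_choice, (g, g, g)), axis=1)

    bulk = world.is_bulk
    cid = world.cluster_id
    for k, s in enumerate(seeds):
        bulk[tuple(s)] = True
        cid[tuple(s)] = k

    # frontier: medium patches adjacent to bulk, as a lazily-cleaned list
    frontier: list[tuple] = []
    in_frontier: set = set()

    def push_neighbors(c):
        for off in MOORE_OFFSETS:
            nb = tuple((np.asarray(c) + off) % g)
            if not bulk[nb] and nb not in in_frontier:
                frontier.append(nb)
                in_frontier.add(nb)

    for s in seeds:
        push_neighbors(tuple(s))

    placed = n_seeds
    while placed < n_bulk:
        if not frontier:
            raise RuntimeError("cluster growth exhausted the frontier")
        j = rng.integers(len(frontier))
        c = frontier[j]
        frontier[j] = frontier[-1]
        frontier.pop()
        in_frontier.discard(c)
        if bulk[c]:
            continue
        # adopt the cluster id of a uniformly chosen bulk neighbour
        nbs = [(tuple((np.asarray(c) + off) % g)) for off in MOORE_OFFSETS]
        bulk_nbs = [nb for nb in nbs if bulk[nb]]
        pick = bulk_nbs[rng.integers(len(bulk_nbs))]
        bulk[c] = True
        cid[c] = cid[pick]
        placed += 1
        push_neighbors(c)


def build_world(config: WorldConfig, seed: int) -> World:
    """Construct the initial world: clustered bulk mineral, agents placed
    uniformly at random on medium patches, free fully-oxidised nanoparticles
    at the shedding-diameter size."""
    config.validate()
    world = World(config, seed)
    g = config.grid_side
    n_patches = g**3
    n_bulk = round(config.fe_patch_percentage / 100.0 * n_patches)
    if n_bulk > n_patches:
        raise ValueError("requested more bulk patches than patches exist")
    if n_bulk >= n_patches:
        raise ValueError("world must retain at least one medium patch")

    _place_bulk_clusters(world, n_bulk)
    world.fe3[world.is_bulk] = config.bulk_fe3_per_patch
    world._finalise_lattice()

    rng = world.rng
    for _ in range(config.initial_number_fe3reducer):
        world.reducers.append(
            Reducer(position=world.random_medium_position(),
                    heading=random_unit_vectors(rng, 1)[0])
        )
    for _ in range(config.initial_number_fe2oxidizer):
        world.oxidizers.append(
            Oxidizer(position=world.random_medium_position(),
                     heading=random_unit_vectors(rng, 1)[0])
        )
    np_iron = np_iron_from_diameter(
        config.shedding_diameter, config.iron_per_cubicnm, config.unit_scale
    ) if config.initial_number_nanoparticle else 0.0
    for _ in range(config.initial_number_nanoparticle):
        world.nps.add(
            fe3=np_iron, fe2=0.0,
            pos=world.random_medium_position(),
            heading=random_unit_vectors(rng, 1)[0],
        )
    return world


# ----------------------------------------------------------------------
def advance_tick(world: World, schedule: OxicSchedule) -> World:
    """Run one minute of model time: movement, redox (gated by the oxic
    state), dissociation, equilibration, particle loss and the aging clock."""
    from . import exchange, movement, redox  # deferred to avoid import cycle

    if world.tick >= world.cfg.max_ticks:
        raise ValueError("advance_tick called past max_ticks")
    world.oxic = schedule.state_at(world.tick) == OXIC

    movement.movement_step(world)
    if world.oxic:
        redox.biotic_oxidation_step(world)
        redox.abiotic_oxidation_step(world)
    else:
        redox.reduction_step(world)
    exchange.dissociation_step(world)
    exchange.equilibrate(world)
    exchange.np_loss(world)
    exchange.aging_step(world)

    world.tick += 1
    return world
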