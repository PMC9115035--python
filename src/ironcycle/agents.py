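"""Agent types and nanoparticle geometry.

Nanoparticles are spheres whose iron content and diameter are linked through the
``iron_per_cubicnm`` density:  ``iron * unit_scale = pi/6 * d^3 * iron_per_cubicnm``.
Bacteria carry continuous positions in patch units; patch membership is the
integer truncation of the position.

The simulation engine stores nanoparticles in a structure-of-arrays
(:class:`NanoparticleStore`) so per-tick work is vectorised; the
:class:`Nanoparticle` dataclass is the equivalent single-particle record used by
the scalar rule functions and in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

# bound-state codes used by NanoparticleStore.bound_kind
FREE, BOUND_REDUCER, BOUND_OXIDIZER = 0, 1, 2


def np_diameter_from_iron(total_iron, iron_per_cubicnm, unit_scale=1.0):
    """Diameter (nm) of a spherical particle holding ``total_iron`` iron units."""
    total_iron = np.asarray(total_iron, dtype=float)
    if np.any(total_iron <= 0):
        raise ValueError("total_iron must be > 0")
    if iron_per_cubicnm <= 0 or unit_scale <= 0:
        raise ValueError("iron_per_cubicnm and unit_scale must be > 0")
    d = (6.0 * total_iron * unit_scale / (math.pi * iron_per_cubicnm)) ** (1.0 / 3.0)
    return float(d) if d.ndim == 0 else d


def np_iron_from_diameter(diameter, iron_per_cubicnm, unit_scale=1.0):
    """Inverse of :func:`np_diameter_from_iron` (exact)."""
    diameter = np.asarray(diameter, dtype=float)
    if np.any(diameter <= 0):
        raise ValueError("diameter must be > 0")
    iron = math.pi / 6.0 * diameter**3 * iron_per_cubicnm / unit_scale
    return float(iron) if iron.ndim == 0 else iron


def np_speed(diameter):
    """Diffusive speed (patches/tick): max(50 - 0.5*d, 1)."""
    return np.maximum(50.0 - 0.5 * np.asarray(diameter, dtype=float), 1.0)


def fe3_fraction(fe3, fe2=None):
    """Fe3+ share of total particle iron, in [0, 1].

    Accepts either a particle-like object with ``fe3``/``fe2`` attributes or the
    two amounts (scalars or arrays).
    """
    if fe2 is None:
        fe3, fe2 = fe3.fe3, fe3.fe2
    fe3 = np.asarray(fe3, dtype=float)
    fe2 = np.asarray(fe2, dtype=float)
    total = fe3 + fe2
    if np.any(total <= 0):
        raise ValueError("empty particle: fe3 + fe2 must be > 0")
    out = fe3 / total
    return float(out) if out.ndim == 0 else out


@dataclass
class Nanoparticle:
    """A single mobile iron oxyhydroxide particle."""

    fe3: float
    fe2: float = 0.0
    bound_to: object = None          # None | ("reducer"|"oxidizer", index)
    ticks_since_reduction: int = 0
    susceptibility: float = 1.0

    @property
    def total_iron(self) -> float:
        return self.fe3 + self.fe2

    def diameter(self, iron_per_cubicnm: float, unit_scale: float = 1.0) -> float:
        return np_diameter_from_iron(self.total_iron, iron_per_cubicnm, unit_scale)


@dataclass
class Reducer:
    """Fe3+-reducing bacterium (Shewanella-like)."""

    position: np.ndarray
    heading: np.ndarray
    attached_patch: tuple | None = None
    ticks_attached: int = 0
    chemotactic_timer: int = 0
    bound_nps: list = field(default_factory=list)

    @property
    def attached(self) -> bool:
        return self.attached_patch is not None


@dataclass
class Oxidizer:
    """Fe2+-oxidizing bacterium (Sideroxydans-like)."""

    position: np.ndarray
    heading: np.ndarray
    surface_nps: list = field(default_factory=list)


class NanoparticleStore:
    """Structure-of-arrays nanoparticle registry with slot reuse.

    Indices of removed particles are recycled, so an index handed out by
    :meth:`add` stays valid until the particle is removed.
    """

    def __init__(self, capacity: int = 256):
        capacity = max(capacity, 16)
        self._cap = capacity
        self.fe3 = np.zeros(capacity)
        self.fe2 = np.zeros(capacity)
        self.pos = np.zeros((capacity, 3))
        self.heading = np.zeros((capacity, 3))
        self.bound_kind = np.zeros(capacity, dtype=np.int8)
        self.host = np.full(capacity, -1, dtype=np.int32)
        self.clock = np.zeros(capacity, dtype=np.int32)  # ticks since last reduction
        self.alive = np.zeros(capacity, dtype=bool)
        self._free_slots: list[int] = []
        self._high = 0  # high-water mark

    # -- bookkeeping ---------------------------------------------------
    def _grow(self, need: int) -> None:
        new_cap = max(self._cap * 2, self._cap + need)
        for name in ("fe3", "fe2", "bound_kind", "host", "clock", "alive"):
            arr = getattr(self, name)
            new = np.zeros(new_cap, dtype=arr.dtype)
            if name == "host":
                new[:] = -1
            new[: self._cap] = arr
            setattr(self, name, new)
        for name in ("pos", "heading"):
            arr = getattr(self, name)
            new = np.zeros((new_cap, 3))
            new[: self._cap] = arr
            setattr(self, name, new)
        self._cap = new_cap

    def add(self, fe3, fe2, pos, heading, bound_kind=FREE, host=-1) -> int:
        if fe3 + fe2 <= 0:
            raise ValueError("a nanoparticle must hold some iron")
        if self._free_slots:
            i = self._free_slots.pop()
        else:
            if self._high >= self._cap:
                self._grow(1)
            i = self._high
            self._high += 1
        self.fe3[i] = fe3
        self.fe2[i] = fe2
        self.pos[i] = pos
        self.heading[i] = heading
        self.bound_kind[i] = bound_kind
        self.host[i] = host
        self.clock[i] = 0
        self.alive[i] = True
        return i

    def remove(self, i: int) -> None:
        if not self.alive[i]:
            raise KeyError(f"nanoparticle {i} is not alive")
        self.alive[i] = False
        self.bound_kind[i] = FREE
        self.host[i] = -1
        self._free_slots.append(i)

    # -- queries -------------------------------------------------------
    @property
    def count(self) -> int:
        return int(self.alive.sum())

    def indices(self, kind=None) -> np.ndarray:
        mask = self.alive[: self._high].copy()
        if kind is not None:
            mask &= self.bound_kind[: self._high] == kind
        return np.flatnonzero(mask)

    def total_iron(self, idx) -> np.ndarray:
        return self.fe3[idx] + self.fe2[idx]

    def diameters(self, idx, iron_per_cubicnm, unit_scale) -> np.ndarray:
        # unchecked fast path: the fe3+fe2 > 0 invariant holds for live slots
        return (
            6.0 * self.total_iron(idx) * unit_scale / (math.pi * iron_per_cubicnm)
        ) ** (1.0 / 3.0)

    def iron_sum(self) -> float:
        idx = self.indices()
        return float(self.fe3[idx].sum() + self.fe2[idx].sum())

    def as_particle(self, i: int) -> Nanoparticle:
        """Materialise one slot as a :class:`Nanoparticle` record (copy)."""
        kind = int(self.bound_kind[i])
        bound = None
        if kind == BOUND_REDUCER:
            bound = ("reducer", int(self.host[i]))
        elif kind == BOUND_OXIDIZER:
            bound = ("oxidizer", int(self.host[i]))
        return Nanoparticle(
            fe3=float(self.fe3[i]),
            fe2=float(self.fe2[i]),
            bound_to=bound,
            ticks_since_reduction=int(self.clock[i]),
        )


def random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniformly random 3-D headings (isotropic)."""
    v = rng.normal(size=(n, 3))
    if n == 1:
        s = math.sqrt(v[0, 0] ** 2 + v[0, 1] ** 2 + v[0, 2] ** 2) or 1.0
        return v / s
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return v / norm
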