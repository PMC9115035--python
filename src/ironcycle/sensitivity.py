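"""Variance-based global sensitivity analysis.

Saltelli's second-order sampling scheme (N base samples over 2k quasi-random
dimensions, radial recombination into N*(2k+2) model evaluations) with the
standard estimators: S1 via Saltelli et al. (2010), ST via Jansen, and the
second-order closed estimator for S2.  Confidence half-widths come from
bootstrap resampling of the base samples.

The design layout is: rows 0..N-1 = A, N..2N-1 = B, then k blocks of N rows
AB_i (A with column i from B), then k blocks BA_i (B with column i from A).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import networkx as nx
from scipy.stats import qmc

#: the 13 process parameters screened in the full-model analysis: the Table-1
#: catalogue minus world-setup/simulation-control entries and the two
#: literature-fixed motility speeds.
DEFAULT_SENSITIVITY_PARAMETERS = [
    "iron_per_cubicnm",
    "mineral_aggregation_probability",
    "contact_reduction_rate",
    "fe2_ads_tolerance",
    "np_mineral_reduction_ratio",
    "abiotic_oxidation_ratio",
    "np_attachment_threshold",
    "np_dissociation_threshold",
    "shedding_diameter",
    "fe2_equilibrium_rate",
    "e_shuttle_range",
    "fe2_solid_ineq",
    "contact_oxidation_rate",
]


@dataclass
class ParamSpace:
    names: list
    bounds: list  # per-parameter (low, high)

    def __post_init__(self):
        if len(self.names) != len(set(self.names)):
            raise ValueError("parameter names must be unique")
        if len(self.bounds) != len(self.names):
            raise ValueError("one (low, high) pair per name required")
        for name, (lo, hi) in zip(self.names, self.bounds):
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy low < high")

    @property
    def k(self) -> int:
        return len(self.names)

    @classmethod
    def around_estimates(cls, estimates: dict, rel: float = 0.2) -> "ParamSpace":
        """Uniform bounds estimate*(1 -/+ rel) per parameter."""
        names = list(estimates)
        bounds = [(v * (1 - rel), v * (1 + rel)) for v in estimates.values()]
        return cls(names=names, bounds=bounds)

    @classmethod
    def default_model_space(cls, config, rel: float = 0.2) -> "ParamSpace":
        est = {n: getattr(config, n) for n in DEFAULT_SENSITIVITY_PARAMETERS}
        return cls.around_estimates(est, rel)


@dataclass
class SobolResult:
    names: list
    S1: np.ndarray
    S1_conf: np.ndarray
    ST: np.ndarray
    ST_conf: np.ndarray
    S2: np.ndarray        # (k, k), upper triangle populated
    S2_conf: np.ndarray

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "S1": self.S1.tolist(),
            "S1_conf": self.S1_conf.tolist(),
            "ST": self.ST.tolist(),
            "ST_conf": self.ST_conf.tolist(),
            "S2": self.S2.tolist(),
            "S2_conf": self.S2_conf.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# ----------------------------------------------------------------------
def saltelli_sample(space: ParamSpace, N: int, seed: int = 0) -> np.ndarray:
    """Design matrix of shape (N*(2k+2), k) within the space's bounds."""
    if N <= 0:
        raise ValueError("N must be a positive integer")
    k = space.k
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # non power-of-two N
        sampler = qmc.Sobol(d=2 * k, scramble=True, seed=seed)
        base = sampler.random(N)
    A, B = base[:, :k], base[:, k:]
    blocks = [A, B]
    for i in range(k):
        AB = A.copy()
        AB[:, i] = B[:, i]
        blocks.append(AB)
    for i in range(k):
        BA = B.copy()
        BA[:, i] = A[:, i]
        blocks.append(BA)
    design01 = np.vstack(blocks)
    lo = np.array([b[0] for b in space.bounds])
    hi = np.array([b[1] for b in space.bounds])
    return lo + design01 * (hi - lo)


def _split(outputs: np.ndarray, N: int, k: int):
    fA = outputs[0:N]
    fB = outputs[N:2 * N]
    fAB = np.stack([outputs[(2 + i) * N:(3 + i) * N] for i in range(k)], axis=1)
    fBA = np.stack([outputs[(2 + k + i) * N:(3 + k + i) * N] for i in range(k)], axis=1)
    return fA, fB, fAB, fBA


def _estimate(fA, fB, fAB, fBA):
    k = fAB.shape[1]
    # centre on the A/B mean so the estimators are exactly shift-invariant
    mu = np.mean(np.r_[fA, fB])
    fA, fB, fAB, fBA = fA - mu, fB - mu, fAB - mu, fBA - mu
    V = np.var(np.r_[fA, fB])
    if V <= 0 or not np.isfinite(V):
        z = np.zeros(k)
        return z, z.copy(), np.zeros((k, k))
    S1 = np.mean(fB[:, None] * (fAB - fA[:, None]), axis=0) / V
    ST = 0.5 * np.mean((fA[:, None] - fAB) ** 2, axis=0) / V
    S2 = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            Vij = np.mean(fBA[:, i] * fAB[:, j] - fA * fB)
            S2[i, j] = Vij / V - S1[i] - S1[j]
    return S1, ST, S2


def sobol_indices(outputs: np.ndarray, space: ParamSpace, N: int,
                  n_boot: int = 100, conf_level: float = 0.95,
                  seed: int = 0) -> SobolResult:
    """First-, second- and total-order Sobol indices with bootstrap
    confidence half-widths.  ``outputs`` must follow the layout produced by
    :func:`saltelli_sample` and contain no missing values."""
    outputs = np.asarray(outputs, dtype=float)
    k = space.k
    if outputs.shape != (N * (2 * k + 2),):
        raise ValueError(
            f"expected {N * (2 * k + 2)} outputs for N={N}, k={k}; "
            f"got {outputs.shape}"
        )
    if np.any(~np.isfinite(outputs)):
        raise ValueError("outputs contain missing/non-finite values")
    fA, fB, fAB, fBA = _split(outputs, N, k)
    S1, ST, S2 = _estimate(fA, fB, fAB, fBA)

    rng = np.random.default_rng(seed)
    zq = 1.959963984540054  # 97.5% normal quantile for the default level
    if conf_level != 0.95:
        from scipy.stats import norm
        zq = norm.ppf(0.5 + conf_level / 2.0)
    b1 = np.empty((n_boot, k))
    bt = np.empty((n_boot, k))
    b2 = np.empty((n_boot, k, k))
    for b in range(n_boot):
        r = rng.integers(0, N, size=N)
        s1, st, s2 = _estimate(fA[r], fB[r], fAB[r], fBA[r])
        b1[b], bt[b], b2[b] = s1, st, s2
    return SobolResult(
        names=list(space.names),
        S1=S1, S1_conf=zq * b1.std(axis=0, ddof=1),
        ST=ST, ST_conf=zq * bt.std(axis=0, ddof=1),
        S2=S2, S2_conf=zq * b2.std(axis=0, ddof=1),
    )


# ----------------------------------------------------------------------
def evaluate_batch(design: np.ndarray, space: ParamSpace, extractor,
                   config=None, schedule=None, base_seed: int = 0,
                   progress: bool = False) -> np.ndarray:
    """One scalar model output per design row.

    ``extractor`` is either a name from :data:`OUTPUT_EXTRACTORS`
    ("last_anoxic_reduction_rate" or "final_np_count") or a callable
    ``(series, schedule) -> float``.  Row seeds derive deterministically from
    ``base_seed`` and the row index.  A failed run yields NaN with a warning;
    :func:`sobol_indices` refuses NaN, so failures must be handled upstream."""
    from .config import default_config
    from .experiments import run_simulation

    if isinstance(extractor, str):
        extractor = OUTPUT_EXTRACTORS[extractor]
    if config is None:
        config = default_config()
    if schedule is None:
        schedule = default_schedule_for(config.max_ticks)
    out = np.empty(len(design))
    for r, row in enumerate(design):
        overrides = {n: float(v) for n, v in zip(space.names, row)}
        seed = (base_seed + 1_000_003 * r) % (2**31 - 1)
        try:
            cfg = config.with_overrides(**overrides)
            series = run_simulation(cfg, schedule, seed)
            out[r] = extractor(series, schedule)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"design row {r} failed: {exc}")
            out[r] = np.nan
    return out


def default_schedule_for(max_ticks: int):
    """Short oxic/anoxic cycling when the run length allows it, otherwise a
    single anoxic phase."""
    from .experiments import cycling_schedules
    from .schedule import ANOXIC, OxicSchedule

    if max_ticks >= 480 and max_ticks % 480 == 0:
        return cycling_schedules(max_ticks, short=True)
    return OxicSchedule(((0, ANOXIC),))


def last_anoxic_reduction_rate(series, schedule) -> float:
    from .experiments import summarize_phases
    phases = summarize_phases(series, schedule)
    anoxic = phases[phases["state"] == "anoxic"]
    if len(anoxic) == 0:
        return 0.0
    return float(anoxic["reduction_rate"].iloc[-1])


def final_np_count(series, schedule) -> float:
    return float(series["np_count"].iloc[-1])


OUTPUT_EXTRACTORS = {
    "last_anoxic_reduction_rate": last_anoxic_reduction_rate,
    "final_np_count": final_np_count,
}


# ----------------------------------------------------------------------
def interaction_network(result: SobolResult, threshold: float = 0.01) -> nx.Graph:
    """Graph of pairwise interactions: nodes carry the S1/ST ratio (the share
    of a parameter's total effect that is direct), edges the S2 values at or
    above the threshold."""
    g = nx.Graph()
    for i, name in enumerate(result.names):
        st = result.ST[i]
        ratio = float(np.clip(result.S1[i] / st, 0.0, 1.0)) if st > 0 else 0.0
        g.add_node(name, S1=float(result.S1[i]), ST=float(st), s1_st_ratio=ratio)
    k = len(result.names)
    for i in range(k):
        for j in range(i + 1, k):
            w = result.S2[i, j]
            if w >= threshold:
                g.add_edge(result.names[i], result.names[j], weight=float(w))
    return g


def edge_list(network: nx.Graph):
    """(source, target, weight) rows for CSV export."""
    return [(u, v, d["weight"]) for u, v, d in network.edges(data=True)]
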