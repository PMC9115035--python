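"""Scenario presets, simulation driver, metrics extraction and replicate
aggregation.

``run_simulation`` produces a tidy per-tick DataFrame of the observables the
model is interrogated about: pool sizes per Fe2+ phase, nanoparticle counts
and composition, the attached-FeRB fraction and the cumulative redox
counters.  ``replicate_runner`` aggregates independent seeds elementwise."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .agents import FREE
from .config import WorldConfig
from .schedule import ANOXIC, OXIC, OxicSchedule
from .world import World, advance_tick, build_world

METRIC_COLUMNS = [
    "tick", "oxic",
    "fe2_dissolved", "fe2_ads_total", "fe2_np_total", "fe2_total",
    "fe3_np_total", "fe3_bulk_total",
    "np_count", "np_free_count", "mean_np_diameter",
    "frac_ferb_attached", "mean_np_per_ferb", "mean_np_fe2_fraction",
    "cum_reduced", "cum_np_reduced", "cum_biotic_ox", "cum_abiotic_ox",
    "removed_iron", "iron_total",
]


def capture_row(world: World) -> dict:
    nps = world.nps
    idx = nps.indices()
    n_np = len(idx)
    cfg = world.cfg
    fe2_np = float(nps.fe2[idx].sum()) if n_np else 0.0
    fe3_np = float(nps.fe3[idx].sum()) if n_np else 0.0
    if n_np:
        d = nps.diameters(idx, cfg.iron_per_cubicnm, cfg.unit_scale)
        mean_d = float(d.mean())
        mean_frac2 = float(np.mean(nps.fe2[idx] / nps.total_iron(idx)))
    else:
        mean_d = 0.0
        mean_frac2 = 0.0
    n_red = len(world.reducers)
    attached = sum(r.attached for r in world.reducers)
    bound = sum(len(r.bound_nps) for r in world.reducers)
    fe2_ads_total = float(world.fe2_ads.sum())
    return {
        "tick": world.tick,
        "oxic": bool(world.oxic),
        "fe2_dissolved": world.dissolved_fe2,
        "fe2_ads_total": fe2_ads_total,
        "fe2_np_total": fe2_np,
        "fe2_total": world.dissolved_fe2 + fe2_ads_total + fe2_np,
        "fe3_np_total": fe3_np,
        "fe3_bulk_total": float(world.fe3.sum()),
        "np_count": n_np,
        "np_free_count": len(nps.indices(kind=FREE)),
        "mean_np_diameter": mean_d,
        "frac_ferb_attached": attached / n_red if n_red else 0.0,
        "mean_np_per_ferb": bound / n_red if n_red else 0.0,
        "mean_np_fe2_fraction": mean_frac2,
        "cum_reduced": world.cum_reduced,
        "cum_np_reduced": world.cum_np_reduced,
        "cum_biotic_ox": world.cum_biotic_ox,
        "cum_abiotic_ox": world.cum_abiotic_ox,
        "removed_iron": world.removed_iron,
        "iron_total": world.iron_total(),
    }


def run_simulation(config: WorldConfig, schedule: OxicSchedule, seed: int,
                   return_world: bool = False):
    """Run ``config.max_ticks`` minutes; one row per tick plus the initial
    state.  Deterministic for a given (config, schedule, seed)."""
    world = build_world(config, seed)
    world.oxic = schedule.state_at(0) == OXIC
    rows = [capture_row(world)]
    for _ in range(config.max_ticks):
        advance_tick(world, schedule)
        rows.append(capture_row(world))
    df = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    return (df, world) if return_world else df


def replicate_runner(config: WorldConfig, schedule: OxicSchedule,
                     n: int, base_seed: int) -> pd.DataFrame:
    """Elementwise mean and sample sd over replicates seeded
    base_seed..base_seed+n-1.  Columns are ``<metric>_mean``/``<metric>_sd``."""
    if n < 1:
        raise ValueError("need at least one replicate")
    runs = [run_simulation(config, schedule, base_seed + i) for i in range(n)]
    stack = np.stack([r.to_numpy(dtype=float) for r in runs])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    out = {}
    for j, col in enumerate(METRIC_COLUMNS):
        out[f"{col}_mean"] = mean[:, j]
        out[f"{col}_sd"] = sd[:, j]
    agg = pd.DataFrame(out)
    agg.insert(0, "tick", runs[0]["tick"].to_numpy())
    return agg


# ----------------------------------------------------------------------
def summarize_phases(series: pd.DataFrame, schedule: OxicSchedule) -> pd.DataFrame:
    """Per-phase mean rates from the cumulative counters.

    A phase [t0, t1) contributes (cum[t1] - cum[t0]) / (t1 - t0); reduction
    rates are reported for anoxic phases, oxidation rates for oxic ones."""
    if len(series) == 0:
        raise ValueError("empty series")
    end = int(series["tick"].iloc[-1])
    by_tick = series.set_index("tick")
    rows = []
    for k, (t0, t1, state) in enumerate(schedule.segments(end)):
        dur = t1 - t0
        if dur <= 0:
            continue
        def rate(col):
            return (by_tick.loc[t1, col] - by_tick.loc[t0, col]) / dur
        rows.append({
            "phase": k,
            "state": state,
            "start": t0,
            "end": t1,
            "reduction_rate": rate("cum_reduced") if state == ANOXIC else 0.0,
            "np_reduction_rate": rate("cum_np_reduced") if state == ANOXIC else 0.0,
            "biotic_ox_rate": rate("cum_biotic_ox") if state == OXIC else 0.0,
            "abiotic_ox_rate": rate("cum_abiotic_ox") if state == OXIC else 0.0,
        })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# presets
PH_PRESETS = {
    # abiotic oxidation: low / medium / high with pH; Shewanella adhesion
    # strong only at pH 5 (x10 tolerance); aggregation maximal near the
    # point of zero charge (pH 7.8), collapsing at low pH.
    5: {"abiotic_oxidation_ratio": 0.001,
        "fe2_ads_tolerance": 3000.0,
        "mineral_aggregation_probability": 1.0},
    6: {"abiotic_oxidation_ratio": 0.003,
        "fe2_ads_tolerance": 300.0,
        "mineral_aggregation_probability": 10.0},
    7: {"abiotic_oxidation_ratio": 0.01,
        "fe2_ads_tolerance": 300.0,
        "mineral_aggregation_probability": 100.0},
}

MODE_COMBOS = {
    1: ("electrostatic", "shedding"),
    2: ("electrostatic", "low_ph"),
    3: ("biofilm", "shedding"),
    4: ("biofilm", "low_ph"),
}


def ph_preset(ph: int) -> dict:
    """Config overrides for the pH scenarios (5, 6 or 7)."""
    try:
        return dict(PH_PRESETS[ph])
    except KeyError:
        raise ValueError(f"no preset for pH {ph}; choose from {sorted(PH_PRESETS)}")


def mode_combo(k: int) -> dict:
    """Adhesion/encrustation mode combination k in 1..4."""
    try:
        adhesion, encrustation = MODE_COMBOS[k]
    except KeyError:
        raise ValueError(f"mode combination must be 1..4, got {k}")
    return {"adhesion_mode": adhesion, "encrustation_mode": encrustation}


def cycling_schedules(total: int = 2880, short: bool = True) -> OxicSchedule:
    """Oxic/anoxic cycling with a fixed 3:1 anoxic:oxic duty cycle.

    short: cycles of 360 min anoxic + 120 min oxic; long: 1080 + 360.  Both
    arms share total time and duty cycle, so only the frequency differs."""
    cycle = 480 if short else 1440
    if total % cycle != 0:
        raise ValueError(f"total {total} not divisible by the cycle length {cycle}")
    anoxic_len = 360 if short else 1080
    points = []
    for start in range(0, total, cycle):
        points.append((start, ANOXIC))
        points.append((start + anoxic_len, OXIC))
    return OxicSchedule(tuple(points))
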