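"""Configuration, schedule and results I/O, plus miniature fixture worlds.

Config files are flat ``key = value`` text (``#`` comments, blank lines
allowed); unknown keys are rejected by name.  The switching schedule is a CSV
with header ``time_min,state``."""

from __future__ import annotations

import csv
from dataclasses import fields
from pathlib import Path

import pandas as pd

from .config import WorldConfig
from .schedule import ANOXIC, OXIC, OxicSchedule

_BOOL_STRINGS = {"true": True, "false": False, "1": True, "0": False,
                 "yes": True, "no": False}


def read_config(path) -> WorldConfig:
    """Parse a flat key-value config, merged over the documented defaults."""
    path = Path(path)
    text = path.read_text()
    types = {f.name: f.type for f in fields(WorldConfig)}
    defaults = WorldConfig()
    overrides = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line:
            key, _, value = line.partition("=")
        elif ":" in line:
            key, _, value = line.partition(":")
        else:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key = key.strip()
        value = value.strip()
        if key not in types:
            raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
        current = getattr(defaults, key)
        try:
            if isinstance(current, bool):
                parsed = _BOOL_STRINGS[value.lower()]
            elif isinstance(current, int):
                parsed = int(value)
            elif isinstance(current, float):
                parsed = float(value)
            else:
                parsed = value
        except (KeyError, ValueError):
            raise ValueError(
                f"{path}:{lineno}: cannot parse {value!r} for key {key!r}"
            ) from None
        overrides[key] = parsed
    return defaults.with_overrides(**overrides)


def write_config(config: WorldConfig, path) -> None:
    lines = [f"{f.name} = {getattr(config, f.name)}" for f in fields(WorldConfig)]
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
def read_schedule_csv(path) -> OxicSchedule:
    path = Path(path)
    points = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ["time_min", "state"]:
            raise ValueError(f"{path}: expected header 'time_min,state'")
        for rowno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ValueError(f"{path}: row {rowno}: expected 2 columns")
            try:
                t = int(row[0])
            except ValueError:
                raise ValueError(
                    f"{path}: row {rowno}: time must be integer minutes"
                ) from None
            state = row[1].strip()
            if state not in (OXIC, ANOXIC):
                raise ValueError(
                    f"{path}: row {rowno}: unknown state {state!r}"
                )
            points.append((t, state))
    try:
        return OxicSchedule(tuple(points))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_schedule_csv(schedule: OxicSchedule, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_min", "state"])
        writer.writerows(schedule.switch_points)


# ----------------------------------------------------------------------
def write_results(series: pd.DataFrame, path) -> None:
    """Tidy CSV, one row per tick (raw run) or per tick with mean/sd columns
    (replicate aggregate)."""
    if len(series) == 0:
        raise ValueError("refusing to write an empty result series")
    series.to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ----------------------------------------------------------------------
def make_fixture_world(kind: str, seed: int = 0):
    """Miniature (config, schedule) pairs for tests and demos.

    empty: 5^3 all-medium world, no agents; single_cluster: 5^3 with one
    compact 27-patch cluster and one reducer; minimal_cycle: 7^3 with two
    reducers, two oxidizers and one anoxic+oxic cycle."""
    if kind == "empty":
        cfg = WorldConfig(
            grid_side=5, fe_patch_percentage=0.0, initial_number_fe3reducer=0,
            initial_number_fe2oxidizer=0, initial_number_nanoparticle=0,
            max_ticks=10, np_loss_percentage=0.0,
        )
        sched = OxicSchedule(((0, ANOXIC),))
    elif kind == "single_cluster":
        cfg = WorldConfig(
            grid_side=5, fe_patch_percentage=27 / 125 * 100, fe_clustering=1.0,
            initial_number_fe3reducer=1, initial_number_fe2oxidizer=0,
            initial_number_nanoparticle=0, max_ticks=60, np_loss_percentage=0.0,
        )
        sched = OxicSchedule(((0, ANOXIC),))
    elif kind == "minimal_cycle":
        cfg = WorldConfig(
            grid_side=7, fe_patch_percentage=10.0, fe_clustering=0.8,
            initial_number_fe3reducer=2, initial_number_fe2oxidizer=2,
            initial_number_nanoparticle=5, start_medium_fe2=1000.0,
            max_ticks=60,
        )
        sched = OxicSchedule(((0, ANOXIC), (30, OXIC)))
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return cfg, sched
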