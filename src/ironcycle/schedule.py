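"""Oxic/anoxic switching schedule: a step function over simulated minutes."""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

OXIC, ANOXIC = "oxic", "anoxic"
STATES = (OXIC, ANOXIC)


@dataclass(frozen=True)
class OxicSchedule:
    """Ordered switch points ``(time_min, state)``; intervals are half-open
    ``[t_i, t_{i+1})`` and the first entry must sit at t = 0."""

    switch_points: tuple

    def __post_init__(self):
        pts = tuple((int(t), str(s)) for t, s in self.switch_points)
        object.__setattr__(self, "switch_points", pts)
        if not pts:
            raise ValueError("schedule needs at least one switch point")
        if pts[0][0] != 0:
            raise ValueError("first switch point must be at t = 0")
        times = [t for t, _ in pts]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("switch times must be strictly increasing")
        for _, s in pts:
            if s not in STATES:
                raise ValueError(f"unknown state {s!r}; expected one of {STATES}")

    def state_at(self, t: int) -> str:
        if t < 0:
            raise ValueError("t must be >= 0")
        times = [p[0] for p in self.switch_points]
        return self.switch_points[bisect_right(times, t) - 1][1]

    def segments(self, end: int) -> list[tuple[int, int, str]]:
        """Phases ``(start, stop, state)`` tiling [0, end)."""
        segs = []
        pts = list(self.switch_points) + [(end, None)]
        for (t0, s), (t1, _) in zip(pts, pts[1:]):
            if t0 >= end:
                break
            segs.append((t0, min(t1, end), s))
        return segs


def state_at(schedule: OxicSchedule, t: int) -> str:
    return schedule.state_at(t)


def constant_schedule(state: str) -> OxicSchedule:
    return OxicSchedule(((0, state),))
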