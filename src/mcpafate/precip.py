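"""Precipitation forcing schedules.

Two contrasting regimes with (nearly) matched cumulative input over one year:

* CLR, continuous light rain: the measured average net infiltration rate of
  0.56 mm/d applied throughout.
* HRE, heavy rain events: 0.56 mm/d for the first two days, then two day-long
  events at 40 mm/d (days [2,3) and [5,6)) each followed by two rain-free
  days, and 0.35 mm/d from day 8 onward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CLR_RATE_MM_D = 0.56
HRE_EVENT_RATE_MM_D = 40.0
HRE_TAIL_RATE_MM_D = 0.35


@dataclass(frozen=True)
class PrecipSchedule:
    """Piecewise-constant infiltration forcing.

    ``intervals`` is an ordered list of ``(start [d], end [d], rate [mm/d])``
    tuples that must tile the simulated span contiguously.
    """

    intervals: tuple[tuple[float, float, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        prev_end = None
        for start, end, rate in self.intervals:
            if end <= start:
                raise ValueError("schedule interval must have positive length")
            if rate < 0:
                raise ValueError("infiltration rates must be non-negative")
            if prev_end is not None and abs(start - prev_end) > 1e-12:
                raise ValueError("schedule intervals must be contiguous")
            prev_end = end

    @property
    def t_start(self) -> float:
        return self.intervals[0][0]

    @property
    def t_end(self) -> float:
        return self.intervals[-1][1]

    def rate_at(self, t_days: float) -> float:
        """Infiltration rate [mm/d] at time ``t_days`` (right-continuous)."""
        if t_days < self.t_start or t_days > self.t_end:
            raise ValueError(f"t={t_days} d outside schedule span")
        for start, end, rate in self.intervals:
            if start <= t_days < end:
                return rate
        return self.intervals[-1][2]

    def breakpoints(self) -> np.ndarray:
        """All interval boundaries [d] (forced time-step boundaries)."""
        pts = [self.intervals[0][0]] + [iv[1] for iv in self.intervals]
        return np.array(pts)

    def cumulative_mm(self, t_days: float | None = None) -> float:
        """Cumulative infiltration [mm] from the start up to ``t_days``."""
        if t_days is None:
            t_days = self.t_end
        total = 0.0
        for start, end, rate in self.intervals:
            if t_days <= start:
                break
            total += rate * (min(end, t_days) - start)
        return total

    def truncated(self, t_end: float) -> "PrecipSchedule":
        """Schedule clipped (or extended at the final rate) to ``t_end`` days."""
        out = []
        for start, end, rate in self.intervals:
            if start >= t_end:
                break
            out.append((start, min(end, t_end), rate))
        if out and out[-1][1] < t_end:
            s, e, r = out[-1]
            out[-1] = (s, t_end, r)
        return PrecipSchedule(intervals=tuple(out), label=self.label)


def constant_schedule(rate_mm_d: float, t_end: float = 365.0, label: str = "") -> PrecipSchedule:
    return PrecipSchedule(intervals=((0.0, t_end, rate_mm_d),), label=label)


def build_precip(label: str, t_end: float = 365.0) -> PrecipSchedule:
    """Build the CLR or HRE forcing schedule over ``[0, t_end]`` days."""
    if label == "CLR":
        return constant_schedule(CLR_RATE_MM_D, t_end, label="CLR")
    if label == "HRE":
        intervals = (
            (0.0, 2.0, CLR_RATE_MM_D),
            (2.0, 3.0, HRE_EVENT_RATE_MM_D),
            (3.0, 5.0, 0.0),
            (5.0, 6.0, HRE_EVENT_RATE_MM_D),
            (6.0, 8.0, 0.0),
            (8.0, 365.0, HRE_TAIL_RATE_MM_D),
        )
        return PrecipSchedule(intervals=intervals, label="HRE").truncated(t_end)
    raise ValueError(f"unknown precipitation label {label!r} (expected CLR or HRE)")
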