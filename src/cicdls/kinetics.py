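"""Postprandial kinetics and population statistics.

Extracts per-donor time courses of the immune-complex contribution, locates
the accumulation peak and the return to baseline, and provides the cohort
summary statistics used for the donor tables: mean, population standard
deviation (divisor n), and Welch-style 99% confidence intervals on group
mean differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mixtures import DEFAULT_IC_WINDOW
from .profiling import SampleProfile, window_contribution

__all__ = [
    "TimeCourse",
    "PopulationSummary",
    "GroupDifference",
    "build_timecourse",
    "peak_time",
    "return_to_baseline",
    "population_summary",
    "group_difference",
]


@dataclass(frozen=True)
class TimeCourse:
    """IC-window contribution of one subject at ordered sampling times."""

    subject_id: str
    times_h: tuple
    ic_pct: tuple

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.ic_pct, dtype=float)
        if t.size == 0 or c.shape != t.shape:
            raise ValueError("times_h and ic_pct must be non-empty, equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times_h must be strictly increasing")
        if np.any((c < 0) | (c > 100)):
            raise ValueError("ic_pct values must lie in [0, 100]")
        object.__setattr__(self, "times_h", tuple(t))
        object.__setattr__(self, "ic_pct", tuple(c))


@dataclass(frozen=True)
class PopulationSummary:
    """Mean and population SD (divisor n) of per-subject values."""

    n: int
    mean: float
    sd: float
    values: tuple


@dataclass(frozen=True)
class GroupDifference:
    """Difference of group means (a - b) with a confidence interval."""

    diff: float
    ci_lo: float
    ci_hi: float
    n1: int
    n2: int
    level: float


def build_timecourse(
    profiles: list[SampleProfile], ic_window_nm=DEFAULT_IC_WINDOW
) -> TimeCourse:
    """IC-window contribution per time point from one subject's native profiles."""
    if not profiles:
        raise ValueError("no profiles given")
    subjects = {p.subject_id for p in profiles}
    if len(subjects) != 1:
        raise ValueError("profiles span multiple subjects")
    if any(p.treatment != "native" for p in profiles):
        raise ValueError("time courses are built from native profiles only")
    times = [p.time_h for p in profiles]
    if any(t is None for t in times):
        raise ValueError("every profile needs a time_h")
    if len(set(times)) != len(times):
        raise ValueError("duplicate time point")
    ordered = sorted(profiles, key=lambda p: p.time_h)
    return TimeCourse(
        subject_id=subjects.pop(),
        times_h=tuple(p.time_h for p in ordered),
        ic_pct=tuple(
            window_contribution(p.distribution, ic_window_nm) for p in ordered
        ),
    )


def peak_time(tc: TimeCourse) -> float:
    """Time of the maximal IC contribution; the earliest time on ties."""
    c = np.asarray(tc.ic_pct)
    return float(tc.times_h[int(np.argmax(c))])


def return_to_baseline(tc: TimeCourse, tolerance_pct: float = 2.0):
    """Earliest post-peak time at which the IC level is back at baseline.

    Baseline is the pre-meal (t = 0) value; "back" means within
    ``tolerance_pct`` percentage points above it.  The default of 2
    percentage points is about three standard deviations of the
    repeat-sampling scatter of the IC contribution (donor variability plus
    inversion error) at default pipeline settings.  Returns the time in
    hours, or the string ``"not returned"`` if the course never decays.
    """
    if 0.0 not in tc.times_h:
        raise ValueError("time course must include the pre-meal time 0")
    baseline = tc.ic_pct[tc.times_h.index(0.0)]
    t_peak = peak_time(tc)
    for t, c in zip(tc.times_h, tc.ic_pct):
        if t > t_peak and c <= baseline + tolerance_pct:
            return float(t)
    return "not returned"


def population_summary(values) -> PopulationSummary:
    """Arithmetic mean and population SD (divisor n) of a value list."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty value list")
    return PopulationSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=0)),
        values=tuple(arr),
    )


def group_difference(a, b, level: float = 0.99) -> GroupDifference:
    """Welch difference of means (a - b) with a t confidence interval.

    Uses sample variances (divisor n-1) and the Welch-Satterthwaite degrees
    of freedom.  Zero-variance groups produce a degenerate zero-width
    interval at the point difference.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    diff = float(a.mean() - b.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / a.size + vb / b.size
    if se2 == 0:
        return GroupDifference(diff, diff, diff, int(a.size), int(b.size), level)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    half = float(stats.t.ppf(0.5 + level / 2, df) * np.sqrt(se2))
    return GroupDifference(
        diff, diff - half, diff + half, int(a.size), int(b.size), level
    )
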