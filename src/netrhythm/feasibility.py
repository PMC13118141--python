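"""Feasibility metrics for passive VPN-based monitoring.

Coverage follows the adherence convention of digital phenotyping: an hour
is "active" if at least one byte of traffic was observed in it, the
monitoring window runs from a participant's first to last active hour
(inclusive), and coverage is the fraction of active hours within that
window.  A "valid day" is a local calendar day with at least one active
hour.  Gaps are maximal runs of inactive hours strictly inside the window.

Retention proportions carry Wilson score intervals; cohort mean coverage
carries a seeded percentile-bootstrap interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from netrhythm.flow_io import BinnedSeries

#: Default time-of-day strata: symmetric 6-hour blocks, half-open [start, end).
DEFAULT_STRATA = {
    "night": (0, 6),
    "morning": (6, 12),
    "afternoon": (12, 18),
    "evening": (18, 24),
}


@dataclass
class CoverageSummary:
    """Per-participant monitoring window, coverage, valid days, gaps, strata."""

    participant_id: str
    window_start_hour: int  # flat hour index of first active hour
    window_end_hour: int  # flat hour index of last active hour (inclusive)
    window_hours: int
    active_hours: int
    coverage_fraction: float
    valid_days: int
    gaps: list[float]  # gap durations, hours
    strata_coverage: dict[str, float] = field(default_factory=dict)


def _hourly_activity(series: BinnedSeries) -> np.ndarray:
    """Flat boolean array over the covered span: hour had >= 1 byte."""
    hourly = series if series.bin_width == 60 else series.rebin(60)
    return (hourly.total() > 0).reshape(-1)


def _window(active: np.ndarray) -> tuple[int, int]:
    idx = np.flatnonzero(active)
    if idx.size == 0:
        raise ValueError("no monitoring window: series contains no active hour")
    return int(idx[0]), int(idx[-1])


def hour_coverage(series: BinnedSeries) -> CoverageSummary:
    """Hour-level coverage over the participant's monitoring window.

    The window spans the first through last active hour inclusive; coverage
    is active hours / window hours.  For example, 100 active hours in a
    120-hour window give coverage 0.8333 (83%).

    Raises ``ValueError`` for an all-zero series (no monitoring window).
    """
    active = _hourly_activity(series)
    first, last = _window(active)
    window_hours = last - first + 1
    active_hours = int(active[first : last + 1].sum())
    return CoverageSummary(
        participant_id=series.participant_id,
        window_start_hour=first,
        window_end_hour=last,
        window_hours=window_hours,
        active_hours=active_hours,
        coverage_fraction=active_hours / window_hours,
        valid_days=valid_days(series),
        gaps=gap_lengths(series),
    )


def valid_days(series: BinnedSeries) -> int:
    """Count local calendar days with at least one active hour."""
    hourly = series if series.bin_width == 60 else series.rebin(60)
    return int(((hourly.total() > 0).any(axis=1)).sum())


def gap_lengths(series: BinnedSeries) -> list[float]:
    """Durations (hours) of maximal inactive runs strictly inside the window.

    The active runs and the returned gaps together tile the monitoring
    window exactly; leading/trailing inactivity is outside the window by
    construction and is not a gap.
    """
    active = _hourly_activity(series)
    first, last = _window(active)
    inside = active[first : last + 1]
    gaps: list[float] = []
    run = 0
    for a in inside:
        if a:
            if run:
                gaps.append(float(run))
            run = 0
        else:
            run += 1
    # `inside` ends on an active hour, so no trailing run to flush
    return gaps


def stratify_coverage(
    series: BinnedSeries,
    strata_def: Mapping[str, tuple[int, int]] | None = None,
) -> dict[str, float]:
    """Coverage restricted to time-of-day and weekday/weekend strata.

    ``strata_def`` maps stratum name to a half-open local-hour interval
    ``(start, end)``; the intervals must partition the 24-hour day.  The
    returned dict additionally holds ``weekday`` and ``weekend`` strata
    (weekend = local Saturday + Sunday).  Each stratum's coverage is
    active / eligible hours among window hours falling in the stratum;
    a stratum with no eligible hours reports NaN.
    """
    strata_def = dict(strata_def or DEFAULT_STRATA)
    covered = np.zeros(24, dtype=int)
    for name, (lo, hi) in strata_def.items():
        if not (0 <= lo < hi <= 24):
            raise ValueError(f"stratum {name!r} interval {(lo, hi)} out of range")
        covered[lo:hi] += 1
    if not (covered == 1).all():
        raise ValueError("time-of-day strata must partition the 24-hour day")

    active = _hourly_activity(series)
    first, last = _window(active)
    n_hours = active.size
    hour_of_day = np.arange(n_hours) % 24
    day_index = np.arange(n_hours) // 24
    weekday0 = series.first_day.weekday()  # Monday == 0
    dow = (weekday0 + day_index) % 7
    in_window = np.zeros(n_hours, dtype=bool)
    in_window[first : last + 1] = True

    out: dict[str, float] = {}

    def frac(mask: np.ndarray) -> float:
        elig = mask & in_window
        n = int(elig.sum())
        return float(active[elig].sum() / n) if n else float("nan")

    for name, (lo, hi) in strata_def.items():
        out[name] = frac((hour_of_day >= lo) & (hour_of_day < hi))
    out["weekday"] = frac(dow < 5)
    out["weekend"] = frac(dow >= 5)
    return out


def wilson_interval(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion.

    Uses the closed-form score interval

        (p̂ + z²/2n ± z·sqrt(p̂(1−p̂)/n + z²/4n²)) / (1 + z²/n)

    with z the standard-normal quantile for the stated level
    (z ≈ 1.959964 at 95%).  Bounds lie in [0, 1] and always contain p̂.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError(f"successes {successes} outside [0, {trials}]")
    z = norm.ppf(0.5 + level / 2)
    n = trials
    p = successes / n
    z2n = z * z / n
    center = (p + z2n / 2) / (1 + z2n)
    half = z * np.sqrt(p * (1 - p) / n + z2n / (4 * n)) / (1 + z2n)
    return (max(0.0, center - half), min(1.0, center + half))


def bootstrap_mean_ci(
    values: Sequence[float],
    level: float = 0.95,
    reps: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Seeded percentile-bootstrap confidence interval for the mean."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("bootstrap requires a non-empty sample")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(reps, values.size))
    means = values[idx].mean(axis=1)
    alpha = 1 - level
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass
class RetentionTable:
    """Pipeline counts and retention proportions with Wilson 95% CIs.

    ``proportions`` maps a label to ``(successes, trials, p, lo, hi)``.
    """

    counts: dict[str, int]
    threshold_days: int
    proportions: dict[str, tuple[int, int, float, float, float]]


def retention_summary(
    valid_day_counts: Sequence[int],
    pipeline_counts: Mapping[str, int] | None = None,
    threshold: int = 5,
    level: float = 0.95,
) -> RetentionTable:
    """Retention proportions at a valid-day threshold, with Wilson CIs.

    ``valid_day_counts`` holds per-participant valid-day totals for everyone
    who contributed any traffic.  ``pipeline_counts`` may supply upstream
    funnel counts (e.g. ``consented``, ``completed``); when present,
    retention relative to consented and completion among consented are also
    reported.
    """
    valid_day_counts = list(valid_day_counts)
    contributors = len(valid_day_counts)
    if contributors == 0:
        raise ValueError("no contributors: retention denominator is zero")
    retained = sum(1 for v in valid_day_counts if v >= threshold)
    counts = dict(pipeline_counts or {})
    counts.setdefault("contributed_traffic", contributors)
    counts[f"retained_ge_{threshold}_days"] = retained

    def entry(s: int, n: int) -> tuple[int, int, float, float, float]:
        lo, hi = wilson_interval(s, n, level)
        return (s, n, s / n, lo, hi)

    proportions = {"retained_among_contributors": entry(retained, contributors)}
    consented = counts.get("consented")
    if consented:
        proportions["retained_among_consented"] = entry(retained, consented)
        completed = counts.get("completed")
        if completed is not None:
            proportions["completed_among_consented"] = entry(completed, consented)
    return RetentionTable(counts=counts, threshold_days=threshold, proportions=proportions)


def round_percent(fraction: float) -> int:
    """Report a proportion as a whole percent, rounding halves up."""
    return int(np.floor(fraction * 100 + 0.5))
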