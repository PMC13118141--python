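"""Behavioral rhythm metrics from binned upload traffic.

Upload volume is used as a proxy for user-initiated activity (messages,
posts, searches generate outbound requests).  Each local day's binned
volumes are replaced by their within-day empirical percentiles — a
rank transform invariant to any strictly monotone rescaling of that day's
raw traffic — yielding a days × bins profile matrix comparable across
participants and devices.

Two summary metrics follow:

* day-to-day stability — the mean Pearson correlation between consecutive
  daily percentile profiles (higher = more routine);
* circadian power ratio — the fraction of non-DC periodogram power of the
  concatenated multi-day series at exactly 1 cycle per 24 hours (higher =
  stronger daily rhythm).

Cohorts are clustered in the z-scored (stability, ratio) plane with
k-means, k = 2, separating relatively routine from fragmented rhythms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from netrhythm.flow_io import BinnedSeries


@dataclass
class DailyProfileMatrix:
    """D days × T bins of percentile-normalized upload intensity.

    ``values`` lie in [0, 100] where observed; ``mask`` is True for bins
    inside VPN-on coverage (unobserved bins carry NaN).  ``usable`` flags
    days with at least one observed bin.
    """

    participant_id: str
    values: np.ndarray  # (D, T), NaN where masked out
    mask: np.ndarray  # (D, T) bool, True = observed
    first_day: date
    bin_width: int
    direction: str = "up"
    category: str | None = None

    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    @property
    def bins_per_day(self) -> int:
        return self.values.shape[1]

    def usable_days(self, min_obs_fraction: float = 0.0) -> np.ndarray:
        frac = self.mask.mean(axis=1)
        return (frac > 0) & (frac >= min_obs_fraction)


@dataclass
class RhythmMetrics:
    participant_id: str
    stability: float  # mean consecutive-day profile correlation, [-1, 1]
    circadian_power_ratio: float  # fraction of non-DC power at 1 c/24 h
    n_days_used: int


@dataclass
class ClusterAssignment:
    """k=2 cluster labels over z-scored (stability, ratio) features.

    Label 0 is oriented to the cluster with higher mean stability
    ("more routine")."""

    labels: dict[str, int]
    features: pd.DataFrame  # participant-indexed z-scored features
    centroids: np.ndarray
    dropped_features: list[str] = field(default_factory=list)


def percentile_normalize_day(
    day_values: Sequence[float], mask: Sequence[bool] | None = None
) -> np.ndarray:
    """Within-day rank-percentile transform.

    Each observed bin's volume is replaced by (average rank − 0.5) / n × 100
    over that day's observed bins, so a fully observed constant day maps to
    all-50 and ties share their average rank.  Masked bins propagate as NaN.

    Raises ``ValueError`` when no bin is observed.
    """
    x = np.asarray(day_values, dtype=float)
    obs = np.ones(x.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    n = int(obs.sum())
    if n == 0:
        raise ValueError("all-masked day: no observed bins to normalize")
    out = np.full(x.shape, np.nan)
    ranks = rankdata(x[obs], method="average")
    out[obs] = (ranks - 0.5) / n * 100.0
    return out


def coverage_mask(series: BinnedSeries) -> np.ndarray:
    """Bins inside VPN-on coverage, inferred from hour-level activity.

    A bin counts as observed when its enclosing hour contains at least one
    byte of traffic in either direction (the coverage unit); use this mask
    from the *unfiltered* series when normalizing category-filtered traffic.
    """
    hourly_active = series.rebin(60).total() > 0 if series.bin_width != 60 else series.total() > 0
    per_hour = 60 // series.bin_width
    return np.repeat(hourly_active, per_hour, axis=1)


def build_profile_matrix(
    series: BinnedSeries,
    direction: str = "up",
    mask: np.ndarray | None = None,
    category: str | None = None,
) -> DailyProfileMatrix:
    """Percentile-normalize a binned series into a daily profile matrix.

    Normalization is applied within each local calendar day independently,
    over that day's observed bins only.  ``mask`` marks bins inside VPN-on
    coverage; when omitted it is inferred from the series' own hour-level
    activity.  Days with no observed bin are flagged unusable (all-NaN row).
    """
    if direction == "up":
        raw = series.up
    elif direction == "down":
        raw = series.down
    elif direction == "total":
        raw = series.total()
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if raw.size == 0:
        raise ValueError("empty series")
    obs = coverage_mask(series) if mask is None else np.asarray(mask, dtype=bool)
    if obs.shape != raw.shape:
        raise ValueError(f"mask shape {obs.shape} != series shape {raw.shape}")
    values = np.full(raw.shape, np.nan)
    for d in range(raw.shape[0]):
        if obs[d].any():
            values[d] = percentile_normalize_day(raw[d], obs[d])
    return DailyProfileMatrix(
        participant_id=series.participant_id,
        values=values,
        mask=obs,
        first_day=series.first_day,
        bin_width=series.bin_width,
        direction=direction,
        category=category,
    )


def day_to_day_stability(
    matrix: DailyProfileMatrix, min_obs_fraction: float = 0.5
) -> float:
    """Mean Pearson correlation between consecutive daily profiles.

    Only days with at least ``min_obs_fraction`` observed bins enter; each
    consecutive usable pair contributes the correlation over its jointly
    observed bins (pairs with fewer than 3 joint bins or zero variance are
    skipped).  Returns NaN when no usable pair exists.
    """
    usable = matrix.usable_days(min_obs_fraction)
    vals = matrix.values
    cors = []
    for d in range(matrix.n_days - 1):
        if not (usable[d] and usable[d + 1]):
            continue
        joint = matrix.mask[d] & matrix.mask[d + 1]
        if joint.sum() < 3:
            continue
        a, b = vals[d, joint], vals[d + 1, joint]
        if a.std() == 0 or b.std() == 0:
            continue
        cors.append(float(np.corrcoef(a, b)[0, 1]))
    return float(np.mean(cors)) if cors else float("nan")


def circadian_power_ratio(
    matrix: DailyProfileMatrix,
    min_obs_fraction: float = 0.0,
    per_day_average: bool = False,
) -> float:
    """Fraction of non-DC spectral power at exactly 1 cycle per 24 hours.

    The daily percentile profiles are concatenated (missing bins imputed at
    the within-day mean, 50), mean-centered, and transformed with a plain
    periodogram.  With D whole days of T bins each, 1 cycle/24 h is exactly
    Fourier frequency index D; the ratio is that power over the total
    non-DC power.  With ``per_day_average`` the ratio is instead computed
    per pair of adjacent days and averaged (sensitivity variant).

    Requires at least 2 days.
    """
    usable = matrix.usable_days(min_obs_fraction)
    rows = matrix.values[usable]
    obs = matrix.mask[usable]
    if rows.shape[0] < 2:
        raise ValueError("circadian power ratio requires at least 2 usable days")
    filled = np.where(obs, rows, 50.0)

    def ratio_of(series2d: np.ndarray) -> float:
        D = series2d.shape[0]
        x = series2d.reshape(-1)
        x = x - x.mean()
        power = np.abs(np.fft.rfft(x)) ** 2
        denom = power[1:].sum()
        return float(power[D] / denom) if denom > 0 else float("nan")

    if per_day_average:
        ratios = [ratio_of(filled[d : d + 2]) for d in range(filled.shape[0] - 1)]
        return float(np.nanmean(ratios))
    return ratio_of(filled)


def compute_rhythm_metrics(
    matrix: DailyProfileMatrix, min_obs_fraction: float = 0.5
) -> RhythmMetrics:
    """Bundle stability and circadian power ratio for one participant."""
    usable = matrix.usable_days(min_obs_fraction)
    n_used = int(usable.sum())
    stability = day_to_day_stability(matrix, min_obs_fraction) if n_used >= 2 else float("nan")
    try:
        ratio = circadian_power_ratio(matrix, min_obs_fraction)
    except ValueError:
        ratio = float("nan")
    return RhythmMetrics(
        participant_id=matrix.participant_id,
        stability=stability,
        circadian_power_ratio=ratio,
        n_days_used=n_used,
    )


def cluster_rhythms(
    metrics: Sequence[RhythmMetrics], seed: int | None = None, n_init: int = 50
) -> ClusterAssignment:
    """k-means (k = 2) over z-scored (stability, circadian power ratio).

    Features are standardized per dimension before clustering, making the
    assignment invariant to affine rescaling of the raw metrics.  A
    zero-variance feature is dropped with a warning-equivalent record in
    ``dropped_features``.  Labels are oriented so cluster 0 has the higher
    mean stability (falling back to the first feature kept).
    """
    metrics = [m for m in metrics if np.isfinite(m.stability) and np.isfinite(m.circadian_power_ratio)]
    if len(metrics) < 2:
        raise ValueError("clustering requires at least 2 participants with defined metrics")
    frame = pd.DataFrame(
        {
            "stability": [m.stability for m in metrics],
            "circadian_power_ratio": [m.circadian_power_ratio for m in metrics],
        },
        index=[m.participant_id for m in metrics],
    )
    dropped = [c for c in frame.columns if frame[c].std(ddof=0) == 0]
    kept = frame.drop(columns=dropped)
    if kept.shape[1] == 0:
        # all participants identical: a single effective cluster, label everyone 0
        z = kept
        labels = np.zeros(len(frame), dtype=int)
        centroids = np.zeros((2, 0))
    else:
        z = (kept - kept.mean()) / kept.std(ddof=0)
        km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
        labels = km.fit_predict(z.to_numpy())
        centroids = km.cluster_centers_
        orient_col = "stability" if "stability" in kept.columns else kept.columns[0]
        mean0 = frame.loc[labels == 0, orient_col].mean()
        mean1 = frame.loc[labels == 1, orient_col].mean()
        if mean1 > mean0:
            labels = 1 - labels
            centroids = centroids[::-1]
    zfull = frame.copy()
    for c in frame.columns:
        sd = frame[c].std(ddof=0)
        zfull[c] = 0.0 if sd == 0 else (frame[c] - frame[c].mean()) / sd
    return ClusterAssignment(
        labels=dict(zip(frame.index, (int(l) for l in labels))),
        features=zfull,
        centroids=centroids,
        dropped_features=dropped,
    )


NIGHT_START_HOUR = 20
NIGHT_END_HOUR = 8


def radial_grid(matrix: DailyProfileMatrix) -> pd.DataFrame:
    """Long-format polar encoding of a profile matrix.

    Bin t maps to angle 360·t/T degrees (midnight at 0°, clockwise), day d
    to ring d.  Night covers 20:00–08:00 local; weekend flags come from the
    local calendar.  Suitable for any plotting layer.
    """
    if matrix.n_days == 0:
        raise ValueError("empty profile matrix")
    T = matrix.bins_per_day
    t = np.arange(T)
    angle = 360.0 * t / T
    hour = t * matrix.bin_width / 60.0
    night = (hour >= NIGHT_START_HOUR) | (hour < NIGHT_END_HOUR)
    rows = []
    for d in range(matrix.n_days):
        day = matrix.first_day + timedelta(days=d)
        weekend = day.weekday() >= 5
        for j in range(T):
            rows.append(
                (
                    matrix.participant_id,
                    d,
                    j,
                    angle[j],
                    matrix.values[d, j],
                    bool(night[j]),
                    weekend,
                )
            )
    return pd.DataFrame(
        rows, columns=["participant", "day", "bin", "angle", "value", "night", "weekend"]
    )


def onset_offset(
    day_percentiles: Sequence[float],
    threshold: float = 60.0,
    min_run: int = 3,
    bin_width: int = 10,
) -> tuple[float, float] | None:
    """Daily activity onset/offset from a percentile profile.

    Onset is the start of the first run of at least ``min_run`` bins above
    ``threshold``; offset is the end (exclusive) of the last such run.
    Both are returned as local clock hours in [0, 24] (a uniformly active
    day yields (0.0, 24.0)).  Returns None when no qualifying run exists.
    These defaults (60th percentile, 30 minutes) are heuristic operating
    points, not validated sleep markers.
    """
    x = np.asarray(day_percentiles, dtype=float)
    above = np.where(np.isnan(x), False, x > threshold)
    runs = []
    start = None
    for i, a in enumerate(list(above) + [False]):
        if a and start is None:
            start = i
        elif not a and start is not None:
            if i - start >= min_run:
                runs.append((start, i))
            start = None
    if not runs:
        return None
    onset_bin, _ = runs[0]
    _, offset_bin = runs[-1]
    return onset_bin * bin_width / 60.0, offset_bin * bin_width / 60.0


def sleep_wake_contrast(
    matrix: DailyProfileMatrix,
    sleep_intervals: Sequence[tuple[pd.Timestamp, pd.Timestamp]],
) -> tuple[float, float, float]:
    """Mean percentile in sleep-annotated vs wake bins, and their difference.

    ``sleep_intervals`` are (start, end) local timestamps.  A bin is
    sleep-labeled when its midpoint falls inside any interval.  Returns
    (mean sleep percentile, mean wake percentile, wake − sleep).  Raises
    when the annotations do not overlap any observed bin.
    """
    D, T = matrix.values.shape
    start = pd.Timestamp(matrix.first_day)
    mids = start + pd.to_timedelta(
        (np.arange(D * T) * matrix.bin_width + matrix.bin_width / 2), unit="m"
    )
    sleep = np.zeros(D * T, dtype=bool)
    for s, e in sleep_intervals:
        s = pd.Timestamp(s).tz_localize(None) if pd.Timestamp(s).tzinfo else pd.Timestamp(s)
        e = pd.Timestamp(e).tz_localize(None) if pd.Timestamp(e).tzinfo else pd.Timestamp(e)
        sleep |= (mids >= s) & (mids < e)
    vals = matrix.values.reshape(-1)
    obs = matrix.mask.reshape(-1) & np.isfinite(vals)
    sleep_obs = sleep & obs
    wake_obs = ~sleep & obs
    if not sleep_obs.any() or not wake_obs.any():
        raise ValueError("sleep annotations do not overlap observed bins")
    m_sleep = float(vals[sleep_obs].mean())
    m_wake = float(vals[wake_obs].mean())
    return m_sleep, m_wake, m_wake - m_sleep
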