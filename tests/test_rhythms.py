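"""Percentile profiles, stability, circadian power, clustering, polar grids."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netrhythm import flow_io, rhythms, synthetic
from netrhythm.rhythms import (
    ClusterAssignment,
    DailyProfileMatrix,
    RhythmMetrics,
    build_profile_matrix,
    circadian_power_ratio,
    cluster_rhythms,
    compute_rhythm_metrics,
    day_to_day_stability,
    onset_offset,
    percentile_normalize_day,
    radial_grid,
    sleep_wake_contrast,
)

T = 144  # 10-minute bins per day


def matrix_from(values, mask=None, first_day=date(2024, 3, 4)):
    values = np.asarray(values, dtype=float)
    mask = np.ones_like(values, dtype=bool) if mask is None else np.asarray(mask, bool)
    norm = np.full(values.shape, np.nan)
    for d in range(values.shape[0]):
        if mask[d].any():
            norm[d] = percentile_normalize_day(values[d], mask[d])
    return DailyProfileMatrix(
        participant_id="P1", values=norm, mask=mask, first_day=first_day, bin_width=1440 // values.shape[1]
    )


class TestPercentileNormalize:
    def test_constant_day_maps_to_all_fifty(self):
        out = percentile_normalize_day(np.full(T, 7.0))
        np.testing.assert_allclose(out, 50.0)

    def test_strictly_increasing_four_bins(self):
        out = percentile_normalize_day([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(out, [12.5, 37.5, 62.5, 87.5])

    def test_masked_bins_propagate_nan(self):
        out = percentile_normalize_day([1.0, 5.0, 3.0], mask=[True, False, True])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [25.0, 75.0])

    def test_all_masked_day_rejected(self):
        with pytest.raises(ValueError, match="all-masked"):
            percentile_normalize_day([1.0, 2.0], mask=[False, False])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sort_and_rank_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 50, size=T).astype(float)  # integer volumes force ties
        out = percentile_normalize_day(x)
        # independent oracle: average rank by explicit sorting and tie-grouping
        order = np.argsort(x, kind="stable")
        ranks = np.empty(T)
        i = 0
        while i < T:
            j = i
            while j < T and x[order[j]] == x[order[i]]:
                j += 1
            ranks[order[i:j]] = (i + 1 + j) / 2  # average of ranks i+1..j
            i = j
        np.testing.assert_allclose(out, (ranks - 0.5) / T * 100)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        """The rank transform ignores any strictly monotone rescaling."""
        rng = np.random.default_rng(seed)
        x = rng.exponential(1000, size=48)
        base = percentile_normalize_day(x)
        for f in (np.log1p, np.sqrt, lambda v: 3 * v + 7, lambda v: v**3):
            np.testing.assert_allclose(percentile_normalize_day(f(x)), base, atol=1e-9)


class TestBuildProfileMatrix:
    def test_two_fully_covered_days(self, routine_series_10):
        matrix = build_profile_matrix(routine_series_10, direction="up")
        assert matrix.values.shape == (7, 144)
        assert matrix.mask.all()
        assert np.nanmin(matrix.values) >= 0 and np.nanmax(matrix.values) <= 100

    def test_vpn_off_afternoon_masks_and_renormalizes(self):
        rng = np.random.default_rng(0)
        up = rng.random((1, 144)) * 1000 + 1  # continuous: no ties
        series = flow_io.BinnedSeries("P1", 10, date(2024, 3, 4), -300, up, np.zeros_like(up))
        mask = np.ones((1, 144), dtype=bool)
        mask[0, 72:108] = False  # afternoon off
        matrix = build_profile_matrix(series, mask=mask)
        assert np.isnan(matrix.values[0, 72:108]).all()
        observed = matrix.values[0, mask[0]]
        np.testing.assert_allclose(
            np.sort(observed), (np.arange(1, 109) - 0.5) / 108 * 100
        )

    def test_all_masked_day_flagged_unusable(self):
        up = np.ones((2, 144))
        series = flow_io.BinnedSeries("P1", 10, date(2024, 3, 4), -300, up, np.zeros_like(up))
        mask = np.ones((2, 144), dtype=bool)
        mask[1] = False
        matrix = build_profile_matrix(series, mask=mask)
        assert list(matrix.usable_days()) == [True, False]
        assert np.isnan(matrix.values[1]).all()

    def test_coverage_mask_follows_active_hours(self):
        up = np.zeros((1, 144))
        up[0, :72] = 5  # first 12 hours active
        series = flow_io.BinnedSeries("P1", 10, date(2024, 3, 4), -300, up, np.zeros_like(up))
        mask = rhythms.coverage_mask(series)
        assert mask[0, :72].all() and not mask[0, 72:].any()


class TestStability:
    def test_identical_days_give_one(self):
        rng = np.random.default_rng(1)
        day = rng.random(T)
        matrix = matrix_from(np.tile(day, (5, 1)))
        assert day_to_day_stability(matrix) == pytest.approx(1.0)

    def test_reversed_monotone_day_gives_minus_one(self):
        day = np.arange(T, dtype=float)
        matrix = matrix_from(np.stack([day, day[::-1]]))
        assert day_to_day_stability(matrix) == pytest.approx(-1.0)

    def test_independent_noise_centers_on_zero(self):
        rng = np.random.default_rng(2)
        vals = [
            day_to_day_stability(matrix_from(rng.random((2, T)))) for _ in range(300)
        ]
        assert abs(np.mean(vals)) < 0.05

    def test_undefined_below_two_usable_days(self):
        matrix = matrix_from(np.random.default_rng(0).random((1, T)))
        assert np.isnan(day_to_day_stability(matrix))

    def test_invariant_to_per_day_monotone_rescaling(self):
        rng = np.random.default_rng(3)
        raw = rng.exponential(100, size=(4, T))
        scaled = np.stack([np.sqrt(raw[0]), raw[1] * 9 + 1, np.log1p(raw[2]), raw[3] ** 2])
        assert day_to_day_stability(matrix_from(raw)) == pytest.approx(
            day_to_day_stability(matrix_from(scaled))
        )


class TestCircadianPowerRatio:
    def daily_sin(self, days, cycles_per_day, phase=0.0):
        t = np.arange(days * T)
        x = 50 + 40 * np.sin(2 * np.pi * cycles_per_day * t / T + phase)
        return x.reshape(days, T)

    def test_pure_24h_sinusoid_concentrates_power(self):
        values = self.daily_sin(7, 1.0)
        matrix = DailyProfileMatrix("P", values, np.ones_like(values, bool), date(2024, 3, 4), 10)
        assert circadian_power_ratio(matrix) >= 0.99

    def test_pure_12h_sinusoid_has_no_24h_power(self):
        values = self.daily_sin(7, 2.0)
        matrix = DailyProfileMatrix("P", values, np.ones_like(values, bool), date(2024, 3, 4), 10)
        assert circadian_power_ratio(matrix) <= 0.01

    def test_white_noise_is_spectrally_flat(self):
        rng = np.random.default_rng(8)
        n_nonDC = (7 * T) // 2
        ratios = []
        for _ in range(300):
            vals = rng.random((7, T)) * 100
            matrix = DailyProfileMatrix("P", vals, np.ones_like(vals, bool), date(2024, 3, 4), 10)
            ratios.append(circadian_power_ratio(matrix))
        expected = 1.0 / n_nonDC
        assert np.mean(ratios) == pytest.approx(expected, rel=0.25)

    def test_parseval_power_conservation(self):
        """Total spectral power equals the series variance (Parseval)."""
        rng = np.random.default_rng(9)
        x = rng.random(5 * T) * 100
        x = x - x.mean()
        power = np.abs(np.fft.fft(x)) ** 2
        assert power.sum() / x.size == pytest.approx((x**2).sum())

    def test_short_series_rejected(self):
        vals = np.random.default_rng(0).random((1, T))
        matrix = DailyProfileMatrix("P", vals, np.ones_like(vals, bool), date(2024, 3, 4), 10)
        with pytest.raises(ValueError, match="2 usable days"):
            circadian_power_ratio(matrix)

    def test_per_day_average_variant_agrees_on_pure_signal(self):
        values = self.daily_sin(6, 1.0)
        matrix = DailyProfileMatrix("P", values, np.ones_like(values, bool), date(2024, 3, 4), 10)
        assert circadian_power_ratio(matrix, per_day_average=True) >= 0.99


class TestClusterRhythms:
    def metrics(self, pairs):
        return [
            RhythmMetrics(f"P{i}", s, r, 10) for i, (s, r) in enumerate(pairs)
        ]

    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(1)
        routine = [(0.8 + rng.normal(0, 0.02), 0.5 + rng.normal(0, 0.02)) for _ in range(10)]
        fragmented = [(0.1 + rng.normal(0, 0.02), 0.05 + rng.normal(0, 0.02)) for _ in range(10)]
        assign = cluster_rhythms(self.metrics(routine + fragmented), seed=0)
        labels = [assign.labels[f"P{i}"] for i in range(20)]
        assert labels[:10] == [0] * 10  # cluster 0 = higher stability
        assert labels[10:] == [1] * 10

    def test_identical_participants_single_effective_cluster(self):
        assign = cluster_rhythms(self.metrics([(0.5, 0.3)] * 4), seed=0)
        assert set(assign.labels.values()) == {0}
        assert set(assign.dropped_features) == {"stability", "circadian_power_ratio"}

    def test_invariant_to_affine_feature_rescaling(self):
        rng = np.random.default_rng(2)
        pairs = [(rng.random(), rng.random()) for _ in range(12)]
        base = cluster_rhythms(self.metrics(pairs), seed=3)
        rescaled = [(s * 1000 - 5, r * 0.01 + 99) for s, r in pairs]
        again = cluster_rhythms(self.metrics(rescaled), seed=3)
        assert base.labels == again.labels

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            cluster_rhythms(self.metrics([(0.5, 0.5)]), seed=0)

    def test_recovers_simulated_phenotypes(self, small_cohort):
        cohort, truths = small_cohort
        mets = []
        for pid, frame in flow_io.split_by_participant(cohort).items():
            series = flow_io.bin_traffic(frame, 10, -300)
            mets.append(compute_rhythm_metrics(build_profile_matrix(series, "up")))
        assign = cluster_rhythms(mets, seed=0)
        agree = np.mean(
            [
                (assign.labels[pid] == 0) == (truths[pid].label == "routine")
                for pid in assign.labels
            ]
        )
        assert agree >= 0.9


class TestRadialGrid:
    def test_polar_conventions(self, routine_series_10):
        matrix = build_profile_matrix(routine_series_10)
        grid = radial_grid(matrix)
        assert grid["day"].nunique() == matrix.n_days  # one ring per day
        six_am = grid[(grid["day"] == 0) & (grid["bin"] == 36)]
        assert six_am["angle"].iloc[0] == pytest.approx(90.0)
        day0 = grid[grid["day"] == 0]
        assert day0["night"].sum() == 72  # 20:00-08:00 is half the bins
        angles = day0["angle"].to_numpy()
        assert len(np.unique(angles)) == 144 and angles.min() == 0 and angles.max() < 360

    def test_weekend_flags_follow_calendar(self):
        vals = np.ones((7, T))
        series = flow_io.BinnedSeries("P1", 10, date(2024, 3, 4), -300, vals, vals)  # Monday start
        grid = radial_grid(build_profile_matrix(series))
        weekend_days = set(grid.loc[grid["weekend"], "day"])
        assert weekend_days == {5, 6}  # Saturday, Sunday


class TestOnsetOffset:
    def test_active_block_found_within_one_bin(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(0, 10, T)
        raw[54:102] += 1000  # 09:00-17:00
        day = percentile_normalize_day(raw)
        onset, offset = onset_offset(day)
        assert onset == pytest.approx(9.0, abs=10 / 60)
        assert offset == pytest.approx(17.0, abs=10 / 60)

    def test_uniformly_high_day_spans_midnight_to_midnight(self):
        day = np.linspace(60.5, 100, T)  # everything above threshold
        onset, offset = onset_offset(day)
        assert (onset, offset) == (0.0, 24.0)

    def test_no_qualifying_run_returns_none(self):
        assert onset_offset(np.full(T, 10.0)) is None

    def test_routine_phenotype_onset_near_true_wake(self, routine_participant, routine_series_10):
        _, truth = routine_participant
        matrix = build_profile_matrix(routine_series_10)
        errors = []
        for d in range(matrix.n_days):
            result = onset_offset(matrix.values[d])
            if result is None:
                continue
            wake = truth.sleep_intervals[d][1]
            wake_hours = wake.hour + wake.minute / 60
            errors.append(abs(result[0] - wake_hours))
        assert errors and np.mean(errors) <= 0.5  # within 3 ten-minute bins


class TestSleepWakeContrast:
    def test_identical_distributions_give_near_zero_difference(self):
        rng = np.random.default_rng(1)
        matrix = matrix_from(rng.random((10, T)))
        intervals = [
            (pd.Timestamp("2024-03-04") + pd.Timedelta(days=d, hours=1),
             pd.Timestamp("2024-03-04") + pd.Timedelta(days=d, hours=8))
            for d in range(10)
        ]
        _, _, diff = sleep_wake_contrast(matrix, intervals)
        assert abs(diff) < 5.0

    def test_routine_sleeper_has_positive_contrast(self, routine_participant, routine_series_10):
        _, truth = routine_participant
        matrix = build_profile_matrix(routine_series_10)
        m_sleep, m_wake, diff = sleep_wake_contrast(matrix, truth.sleep_intervals)
        assert diff > 0
        assert m_sleep < 50 < m_wake

    def test_contrast_beats_shuffled_annotations(self, routine_participant, routine_series_10):
        """Observed sleep-wake contrast exceeds the 95th percentile of
        circularly shifted (permuted) annotations."""
        _, truth = routine_participant
        matrix = build_profile_matrix(routine_series_10)
        _, _, observed = sleep_wake_contrast(matrix, truth.sleep_intervals)
        rng = np.random.default_rng(5)
        null = []
        for _ in range(200):
            shift = pd.Timedelta(minutes=int(rng.integers(120, 1320)))
            shifted = [(s + shift, e + shift) for s, e in truth.sleep_intervals]
            try:
                null.append(sleep_wake_contrast(matrix, shifted)[2])
            except ValueError:
                continue
        assert observed > np.percentile(null, 95)

    def test_non_overlapping_annotations_rejected(self):
        matrix = matrix_from(np.random.default_rng(0).random((2, T)))
        far = [(pd.Timestamp("2030-01-01"), pd.Timestamp("2030-01-02"))]
        with pytest.raises(ValueError, match="overlap"):
            sleep_wake_contrast(matrix, far)
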