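"""Behavioral rhythm metrics: percentile profiles, stability, circadian
power, onset/offset, sleep-wake contrast, and phenotype clustering.

Upload traffic is binned at 10 minutes and each day rank-normalized to
percentiles, making profiles comparable across people and devices.
"""

import numpy as np

from netrhythm import flow_io, rhythms, synthetic

cohort, truths = synthetic.simulate_cohort(
    synthetic.CohortConfig(n_participants=8, days=10, seed=11)
)

metrics = []
for pid, frame in flow_io.split_by_participant(cohort).items():
    series = flow_io.bin_traffic(frame, 10, -300)
    matrix = rhythms.build_profile_matrix(series, direction="up")
    m = rhythms.compute_rhythm_metrics(matrix)
    metrics.append(m)
    truth = truths[pid]
    day0 = rhythms.onset_offset(matrix.values[1])
    onset = f"{day0[0]:05.2f}h" if day0 else "  -  "
    sleep, wake, diff = rhythms.sleep_wake_contrast(matrix, truth.sleep_intervals)
    print(
        f"{pid} ({truth.label:10s}): stability={m.stability:5.2f} "
        f"circadian ratio={m.circadian_power_ratio:5.2f} "
        f"day-1 onset={onset} sleep/wake percentile={sleep:4.1f}/{wake:4.1f}"
    )
# Stability is the mean Pearson correlation between consecutive daily
# percentile profiles; the circadian ratio is the share of non-DC spectral
# power at exactly 1 cycle per 24 h.  Both are higher for routine sleepers.

assign = rhythms.cluster_rhythms(metrics, seed=0)
agreement = np.mean(
    [(assign.labels[pid] == 0) == (truths[pid].label == "routine") for pid in assign.labels]
)
print(f"\nk-means (k=2) on z-scored metrics recovers phenotypes: {agreement:.0%} agreement")

# The radial grid export maps each bin to a clock angle (midnight at 0°)
# and each day to a ring, with night (20:00-08:00) and weekend flags.
pid = next(iter(assign.labels))
frame = flow_io.split_by_participant(cohort)[pid]
grid = rhythms.radial_grid(
    rhythms.build_profile_matrix(flow_io.bin_traffic(frame, 10, -300))
)
print(f"Radial grid for {pid}: {len(grid)} cells, columns {list(grid.columns)}")
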