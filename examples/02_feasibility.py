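"""Coverage, valid days, gaps, and retention for a simulated cohort.

An hour is "active" if it contains at least one byte of traffic; coverage
is active hours over the monitoring window (first to last active hour).
Retention at the 5-valid-day threshold carries a Wilson 95% CI, and the
cohort mean coverage a seeded percentile-bootstrap CI.
"""

import numpy as np

from netrhythm import feasibility, flow_io, synthetic

cohort, _ = synthetic.simulate_cohort(
    synthetic.CohortConfig(n_participants=8, days=10, seed=7)
)

coverages, valid = [], []
for pid, frame in flow_io.split_by_participant(cohort).items():
    series = flow_io.bin_traffic(frame, 60, -300)
    cov = feasibility.hour_coverage(series)
    strata = feasibility.stratify_coverage(series)
    coverages.append(cov.coverage_fraction)
    valid.append(cov.valid_days)
    gaps = cov.gaps
    print(
        f"{pid}: window={cov.window_hours:4d} h, coverage={cov.coverage_fraction:6.1%}, "
        f"valid days={cov.valid_days:2d}, gaps={len(gaps):2d} "
        f"(median {np.median(gaps):.1f} h)" if gaps else
        f"{pid}: window={cov.window_hours:4d} h, coverage={cov.coverage_fraction:6.1%}, "
        f"valid days={cov.valid_days:2d}, no gaps"
    )

lo_b, hi_b = feasibility.bootstrap_mean_ci(coverages, reps=5000, seed=1)
table = feasibility.retention_summary(valid, threshold=5)
s, n, p, lo, hi = table.proportions["retained_among_contributors"]
print(f"\nMean coverage {np.mean(coverages):.1%} (bootstrap 95% CI {lo_b:.1%}-{hi_b:.1%})")
print(f"Retention >= 5 valid days: {s}/{n} = {p:.0%} (Wilson 95% CI {lo:.0%}-{hi:.0%})")
# The Wilson interval never escapes [0, 1] and stays informative at small n,
# which is why it is preferred over the normal approximation here.
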