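# netrhythm

Digital phenotyping from encrypted network-traffic metadata.

An on-device VPN can log, for every 10-second window, how many bytes a
smartphone exchanged with each destination hostname — without ever seeing
payloads. `netrhythm` turns such flow-metadata logs into interpretable
behavioral measures for feasibility studies in passive mobile sensing:

* **Feasibility** — monitoring windows, hour-level coverage (an hour is
  *active* if it contains ≥ 1 byte), valid days, VPN off-gap statistics,
  time-of-day / weekend strata, retention proportions with Wilson score
  intervals, and bootstrap CIs for cohort mean coverage.
* **App attribution** — App Privacy Report (APR) corpora give app →
  hostname mappings; hostnames are reduced to registered (base) domains
  under public-suffix rules, and only domains contacted by *exactly one*
  app across the union corpus are retained. The resulting unique-domain
  map is a conservative lower bound on app presence: it can miss, but
  never mislabel.
* **Behavioral rhythms** — upload volume (a proxy for user-initiated
  activity) is binned at 10 minutes and each day rank-normalized: bin
  *t* of day *d* becomes its empirical percentile within
  {x_{d,1}, …, x_{d,T}}, a transform invariant to monotone rescaling.
  From the resulting days × bins profile matrix the package computes
  **day-to-day stability** (mean Pearson correlation between consecutive
  daily profiles) and the **circadian power ratio** (fraction of non-DC
  periodogram power at exactly 1 cycle / 24 h), then clusters the cohort
  with k-means (k = 2) on z-scored metrics into relatively routine vs
  fragmented rhythm phenotypes.
* **Synthetic cohorts** — a first-class generator
  (`netrhythm.synthetic`) emits flow logs, APR-style reports, category
  maps and ground-truth annotations (sleep intervals, app sessions, VPN
  off intervals, phenotype labels) with the statistical structure the
  analyses assume, so every stage is testable without participant data.

## Worked example

```python
import numpy as np
from netrhythm import synthetic, flow_io, feasibility, rhythms

cohort, truths = synthetic.simulate_cohort(
    synthetic.CohortConfig(n_participants=8, days=10, seed=11)
)

metrics = []
for pid, frame in flow_io.split_by_participant(cohort).items():
    series = flow_io.bin_traffic(frame, bin_width=10, tz=-300)
    matrix = rhythms.build_profile_matrix(series, direction="up")
    metrics.append(rhythms.compute_rhythm_metrics(matrix))

assign = rhythms.cluster_rhythms(metrics, seed=0)
agreement = np.mean(
    [(assign.labels[p] == 0) == (truths[p].label == "routine") for p in assign.labels]
)
print(f"phenotype recovery: {agreement:.0%}")
```

Running `python examples/04_rhythms.py` (which adds onset estimates and
sleep–wake contrasts) prints, per participant, lines like

```
SP2c39f4 (routine   ): stability= 0.63 circadian ratio= 0.42 day-1 onset=07.17h sleep/wake percentile=17.6/66.1
SP7f1397 (fragmented): stability= 0.16 circadian ratio= 0.15 day-1 onset=02.67h sleep/wake percentile=27.6/59.8
...
k-means (k=2) on z-scored metrics recovers phenotypes: 100% agreement
```

Routine sleepers show high day-to-day stability (consecutive daily
profiles correlate ≈ 0.6), strong 24-hour spectral concentration
(ratio ≈ 0.4), activity onset tracking their true wake time (~07:30), and
much lower upload percentiles during sleep than wake (≈ 18 vs ≈ 66).
Fragmented phenotypes collapse on all four measures, and the 2-cluster
k-means separates the groups perfectly in this run.

The `examples/` directory holds one short script per capability
(simulation, feasibility, attribution, rhythms, full pipeline); each
prints its results with a note on what they mean. A thin CLI mirrors the
pipeline: `netrhythm simulate|feasibility|attribute|rhythms|run|report`.

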