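# Methods

This note documents the models and procedures `netrhythm` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show.

## Data model

The primitive observation is a **flow record**: one 10-second window of
traffic between a participant's device and one destination hostname,
carrying upload/download byte and packet counts and a timestamp with an
explicit UTC offset. Local time is the timestamp shifted by a fixed
per-participant offset; daylight-saving transitions are not modeled (the
intended analyses restrict to participants who remain in one time zone).
Days are local calendar days bounded at midnight. Records are aggregated
into contiguous, non-overlapping within-day bins — 60 minutes for
coverage work, 10 minutes for rhythm work — by the bin containing the
window start (a 10-second window cannot meaningfully straddle a 10-minute
bin; the assignment error is bounded by 10 s). The dense days × bins grid
guarantees bins tile the covered span and byte totals are conserved.

## Feasibility metrics

* **Active hour**: a 60-minute interval with ≥ 1 observed byte in either
  direction. **Monitoring window**: first through last active hour,
  inclusive. **Coverage** = active / window hours. A series with no
  active hour has no window and is an error, not zero coverage.
* **Valid day**: a local calendar day with ≥ 1 active hour.
* **Gaps**: maximal runs of inactive hours strictly inside the window,
  reported at 1-hour resolution (the coverage unit). Sub-hour outages are
  invisible at this resolution; fractional cohort summaries (e.g. a
  median gap of 7.5 h) arise from aggregating across participants.
* **Strata**: time-of-day coverage uses four symmetric 6-hour blocks —
  night 00–06, morning 06–12, afternoon 12–18, evening 18–24, half-open,
  local time — and weekday/weekend (Saturday + Sunday) from the local
  calendar. The blocks are a configurable convention; per-stratum
  coverage is active / eligible hours within the window, so eligible
  hours across a partition always tile the window.
* **Wilson score interval** for retention proportions, computed in
  closed form with z = Φ⁻¹(0.975) ≈ 1.959964 at the default 95% level.
  Preferred over the Wald interval because it stays inside [0, 1] and
  behaves at the small n typical of feasibility cohorts. Verified in
  tests against `statsmodels.stats.proportion.proportion_confint`.
* **Bootstrap CI for mean coverage**: seeded percentile bootstrap,
  default 10,000 resamples. The percentile method was chosen for
  transparency; it is known to undercover slightly at small samples
  (≈ 93% empirical coverage at n ≈ 30 for a nominal 95% interval), which
  is why the calibration test measures coverage at n = 100, isolating
  implementation correctness from small-sample bootstrap theory.
* Reported proportions round to whole percents, half away from zero.

## App attribution

APR-style corpora map each app to the raw hostnames it contacted.
Hostnames are lowercased, trailing dots stripped, then either rejected
(IP literals, single labels, special-use suffixes such as `.local`,
`.test`, `.arpa`, `.onion`) or reduced to the **registered (base)
domain**: one label below the longest matching public suffix. Suffix
rules come from a small bundled snapshot (no network fetch); a TLD absent
from the snapshot is treated as its own public suffix, mirroring the
public-suffix list's default rule. The snapshot deliberately lists the
documentation TLD `example` as routable so synthetic corpora built on
`*.example` survive normalization.

Over the union corpus of all sources, only domains contacted by exactly
one app are retained (the **unique-domain map**); every other domain is
excluded as shared infrastructure. Because app sets only grow under
union, adding a source can never turn a shared domain unique — the map is
monotonically conservative, and an attributed label can be missing but
never wrong. Attribution coverage is summarized two ways: the fraction
of upload bytes on attributable flows (low, since CDNs carry most
volume), and the fraction of occupied 10-minute bins containing at least
one attributable flow (much higher: timing survives the conservatism).

"Semantically identifiable" — used when comparing scripted-launch corpora
against naturalistic ("deep-state") corpora — is operationalized as: the
app has ≥ 1 unique domain whose registrable label shares an alphanumeric
token (≥ 4 characters) with the app name. The predicate is an explicit,
replaceable stand-in for a human judgment.

## Rhythm metrics

* **Percentile normalization**: within each day, each observed bin's
  upload volume x is replaced by (average rank − 0.5)/n × 100 over that
  day's n observed bins. Ties share their average rank, so a constant
  fully-observed day maps to all-50. The transform is invariant to any
  strictly monotone rescaling of the day's volumes, removing
  between-person and between-device scale differences. Bins outside
  VPN-on coverage (inferred from hour-level activity, or supplied
  explicitly) propagate as missing; normalization is over observed bins
  only.
* **Day-to-day stability**: mean Pearson correlation between consecutive
  daily percentile profiles, over jointly observed bins, restricted to
  days with ≥ 50% observed bins (configurable). Pearson on rank-
  normalized inputs is close to Spearman on the raw volumes; pairs with
  < 3 joint bins or zero variance are skipped. Undefined (NaN) with
  fewer than two usable days.
* **Circadian power ratio**: daily profiles are concatenated (missing
  bins imputed at the within-day mean, 50), mean-centered, and
  transformed with a plain periodogram. With D whole days of T bins,
  1 cycle / 24 h is exactly Fourier index D, so no band-integration is
  needed; the ratio is that power over total non-DC power. A
  per-day-pair averaged variant is available behind a flag for
  sensitivity analysis. Parseval's identity is asserted numerically in
  tests.
* **Clustering**: k-means, k = 2, on z-scored (stability, ratio), with
  k-means++ initialization, 50 restarts, fixed seed. Labels are oriented
  so cluster 0 has the higher mean stability ("more routine"). A
  zero-variance feature is dropped and recorded; if both features are
  degenerate the cohort is a single effective cluster labeled 0.
* **Onset/offset**: first/last run of ≥ 3 consecutive 10-minute bins
  above the 60th percentile. These defaults are heuristic operating
  points, not validated sleep markers, and are exposed as parameters.
* **Radial grid**: bin t ↦ angle 360·t/T (midnight at 0°, clockwise),
  day d ↦ ring d, night mask 20:00–08:00, weekend flags from the local
  calendar; exported long-format for any plotting layer.

## Synthetic cohort generator

The generator defines the conditions under which the pipeline is
validated. Per participant it emits:

* **Background traffic**: per-10-second Bernoulli emission (default
  p = 0.15) to shared OS/infrastructure domains, lognormal byte volumes
  (upload scale 120 B, download 600 B) — heavy-tailed always-on
  keep-alives; phones are never silent, so an undisturbed hour is active
  with near-certainty.
* **Sleep**: one episode per night at a phenotype-specific onset with
  day-to-day Gaussian jitter. During sleep, background upload volume is
  scaled to 10% of the wake rate (a free parameter; no published effect
  size exists to calibrate it). Routine sleepers default to 23:30–07:30
  with 20-minute jitter — episodes deliberately cross midnight, since a
  sleep block entirely inside the calendar day would make the first
  activity run of the day precede sleep rather than follow wake.
  Fragmented phenotypes default to 02:00 onset with 150-minute jitter.
* **App sessions**: Poisson daily counts allocated across the app
  catalog by mix weights, 2–8 minutes long, placed in wake time with an
  evening bump (Gaussian around 20:00) and shifted out of sleep blocks;
  fragmented phenotypes place 35% of sessions inside sleep intervals.
  Session windows alternate between the app's unique domains and shared
  infrastructure, with upload volumes scaled so a session totals tens of
  kilobytes — uploads dominate sessions relative to background, mirroring
  the use of upload volume as an interaction proxy.
* **Morning pickup**: each sleep offset is followed (with probability
  1.0 for routine, 0.5 for fragmented) by a 25–45 minute session burst
  starting within 10 minutes of waking — the near-universal
  phone-in-bed check. This is what gives the day a sharp, sustained
  activity onset at wake for the onset/offset estimator to find.
* **VPN off-gaps**: per-day reboot probability 0.1 with lognormal
  reactivation delay (median 2 h), so short gaps are common and
  multi-day lapses rare; deliberate off intervals can be forced for
  fixture construction. No flow is ever emitted inside an off interval.
* **APR emission**: scripted mode yields each app's unique domains plus
  a random subset of its shared domains; participant (deep-state) mode
  yields unique domains, all shared domains, the full OS-infrastructure
  pool, and any deep-state-only domains. One catalog app ("Quietly") is
  identifiable only through its deep-state domain; one ("PhotoShare")
  carries only an opaque unique domain and is never name-identifiable.

All randomness flows from a single seed; a fixed seed reproduces the
cohort bit-for-bit.

**What passing tests show — and don't.** The generator reproduces the
*structure* the analyses assume (diurnal phase, always-on background,
unique/shared domain mixtures, off-gaps, staggered onboarding), so tests
demonstrate that each method recovers planted parameters under that
structure. Real traffic differs in ways the generator does not emulate:
realistic hostname grammar, bursty non-stationary backgrounds, app
updates shifting domain sets over time, travel and DST, correlated
multi-device usage. Quantities tied to the original deployment's data
(e.g. its 74.1% mean coverage or its 1.47% byte-attribution rate) are
properties of that cohort, not of the method, and are not reproduced
here.

## Problem sizes used in validation

Cohort-level checks run on 24 simulated participants × 14 days
(phenotype-recovery clustering), 4–6 participants × 5 days (attribution
precision, retention), 1,000 random days (normalization oracle), 1,000
day pairs (stability noise floor), 100 random on/off fixtures
(coverage/gap enumeration), and 1,000 replicate experiments of n = 100
(bootstrap calibration). These sizes give the Monte-Carlo margins the
assertions state while keeping the full suite fast.

## Known limitations

* Gap resolution is 1 hour; sub-hour VPN outages are invisible.
* The unique-domain map is a lower bound by design: apps without unique
  domains are unobservable, and byte-level coverage is intentionally
  small.
* Onset/offset estimation presumes a sustained post-wake activity burst;
  users who wake without touching their device will be detected late.
* Stability and the circadian ratio describe regularity of *device
  upload activity*, not sleep or clinical phenotypes; the k = 2
  clustering is a descriptive partition, not a diagnostic.
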