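# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations behind `herdsense`.

## The generative model of the synthetic herd

No public dataset of per-cow pedometer records exists, so the package
simulates one with fully known ground truth. The herd defaults to 147
cows with the reference age distribution (111 young, aged 2–5; 36 old,
aged 6–12) and a latent behavioral cluster per cow (54 active, 83
normal, 10 dormant, with a fixed per-age composition). Daily activity is

> activity = herd baseline + cluster offset + Gaussian daily noise,

then modified by planted welfare events. This is deliberately the
simplest model under which deviation-from-herd-mean profiling and
cluster assignment are identifiable: real activity series have
autocorrelation, weather and management covariates, and herd social
structure, none of which are modeled. Passing tests therefore
demonstrate correctness of the analytics contracts on well-specified
input, not field performance on a real herd.

### Baselines and noise (free parameters, not field estimates)

| parameter | default | unit | note |
|---|---|---|---|
| baseline steps | 5000 | steps/day | typical published pedometer magnitudes |
| baseline lying | 11.0 | h/day | typical adult dairy cow lying budget |
| baseline swaps | 1.5 | /hour | lying↔standing transitions |
| noise SD | 150 / 0.3 / 0.05 | per activity | daily i.i.d. Gaussian |

No reference distributional parameters for real herd activity are
available; these defaults are documented free choices of plausible
magnitude and are not claimed to match any particular farm.

### Cluster offsets

Active: +500 steps, −1.0 h lying, +5/24 swaps·h⁻¹; dormant: −2700
steps, +5.4 h lying, −27/24 swaps·h⁻¹; normal: 0. Two deliberate
constraints shape these values:

1. **Balanced mix.** Weighted by the default 54/83/10 cluster counts the
   offsets cancel (54·active + 10·dormant = 0 per activity), so the herd
   mean coincides with the normal-cluster baseline. Without this, the
   asymmetric active/dormant split would shift the herd mean off the
   majority cluster and a normal cow would show a systematic nonzero
   deviation — under the balanced mix the zero-noise limit (a normal
   cow's three absolute deviations are exactly 0) holds, and the
   uncentered near-threshold vote is well posed.
2. **Quantization compatibility.** Swap offsets are exact multiples of
   1/24 because daily swap totals are integers; steps are integers and
   lying is kept to 4 decimals, which makes the 6-minute stream
   decomposition exactly invertible.

Every offset is at least 3 daily noise SDs from zero, the regime in
which the clustering-recovery and classification properties are stated.

### Planted events

* **Oestrus:** open (non-pregnant) cows cycle every 21 days; the heat
  day multiplies steps by 2.0 and lying by 0.7. The fertile window is
  ~18 h, i.e. one day at daily granularity.
* **Pregnancy/calving:** a configurable fraction (default 0.3) of cows
  are pregnant, with insemination dates placed so calving falls 10–80
  days into the run; gestation is fixed at 283 days (textbook bovine
  mean — a named default, since only insemination date and pregnancy
  stage are tracked conceptually). Lying rises by +3 h on the two days
  before calving.
* **Lameness:** a configurable fraction (default 0.05) of cows get an
  onset 15–45 days in; steps ramp down to −50% and lying ramps up +3 h
  linearly over 5 days.

### Telemetry

Each cow-day decomposes into 240 messages on a fixed 6-minute UTC grid,
299 payload bytes each (240·299 B = 70.08 KiB/sensor/day). Integer
daily counts are apportioned by the largest-remainder method; with equal
per-bin quotas the remainder goes to the earliest bins, which is
deterministic and exactly conserving. Timestamps are UTC; dates are
timezone-free calendar days.

## Profiling and clustering

`C_AD = |Hm − Ca|` per activity per day, with the herd mean taken over
cows that have a record that day. Cluster assignment is a 2-of-3
directional majority over window-mean signed deviations: steps above /
lying below / swaps above the herd mean is the "high-activity" side;
"near" means |window-mean deviation| ≤ τ·dispersion. "Best of three" is
interpreted as this majority vote because it is the only reading
consistent with the stated cluster semantics (active = more steps AND
less lying).

* **Dispersion** is the per-activity median absolute deviation (MAD) of
  the *daily* signed deviations across all cow-days. Daily MAD gives a
  band wide enough to hold essentially all normal cows (window means
  concentrate ≈√window tighter than daily values) while cluster offsets
  ≥3 noise SDs sit far outside it; τ defaults to 1.0.
* **Window** defaults to 7 days. "Rolling" assignment is realized as
  consecutive non-overlapping 7-day windows, which is what the
  migration-anomaly rules need (a sequence of comparable window labels).
  Full-period assignment (one window spanning all dates) is used for
  the age×cluster cross-table.
* **Cross-table percentages** are percentages of the whole herd, rounded
  to the *nearest* whole percent. Note the degenerate cell: a single
  dormant young cow out of 147 is 0.68%, which nearest-rounds to 1%;
  truncation would print 0%. The package uses nearest rounding
  throughout and documents this cell explicitly.
* Daily herd means feed window-averaged deviations (daily-then-averaged)
  rather than a single study-period mean; both are expressible, the
  former is the default because alerting needs windows.

## Alert rules

All thresholds are calibrated defaults exposed in config, not field-
validated claims:

* **Heat:** steps > 1.8× the cow's rolling 7-day median AND lying below
  its rolling median; first qualifying day fires, qualifying days within
  2 days collapse into one alert (debounce). The 7-day median is robust
  to single-day noise; cows with <8 days of history are skipped with a
  logged notice.
* **Migration anomaly:** entry into the dormant cluster within ≤2
  windows of last holding the recent peak label (active or normal);
  declines spread over >3 windows are benign drift and suppressed.
* **Dormant drop:** a dormant cow whose window-mean steps fall below
  0.6× its own previous window.
* **Calving:** inside due-date ±10 days, lying above the rolling median
  by ≥2 h; at most one alert per pregnancy.
* **Routing** is a pure function: SMS when the cloud link is up, on-farm
  audio-visual otherwise; the alert set itself never depends on
  connectivity.

## Store-and-forward semantics

Delivery is at-least-once with (sensor_id, timestamp) deduplication and
per-sensor resume points. The gateway's disk buffer is treated as
unbounded within a run, so cloud outages of any length only delay
delivery; the sole loss mechanism is the sensor's 12-h retention during
a gateway outage — at recovery, messages older than the retention
horizon are gone (a 14-h outage loses exactly its first 2 hours).
No wire protocol (MQTT or otherwise) is implemented; the QoS-1-like
semantics are modeled, not transported. Byte accounting uses
1 KB = 1024 B and 1 MB = 1024² B. The reference daily farm volumes
(10.1 MB raw, 1.62 MB forwarded) are empirical measurements used as
inputs to the reduction arithmetic; 147 × 70 KB does not reproduce
10.1 MB exactly under either MB convention.

## Classification

Cow-days are labeled irregular inside [onset, onset + 3 days] of a
planted lameness event; the 3-day `sign_lag` models the delay until
visual signs. Post-visual days are excluded — they are neither
early-warning positives nor honest negatives. Features per cow-day:
each activity's signed herd-mean deviation re-referenced to the cow's
own 7-day rolling-median baseline, each activity's 3-day deviation
trend, and the current cluster code (+1/0/−1). Signed, self-referenced
deviations were chosen over raw absolute deviations because |·| makes an
onset-day lame cow indistinguishable from a habitually active cow, and a
raw swaps level duplicates the cluster code; anomaly-relevant quantities
are changes, not levels.

The 80/20 split is stratified by label and grouped by cow (no cow spans
both sets) to prevent leakage between adjacent days of the same animal;
a per-day mode exists for comparability. K-NN uses Euclidean distance on
z-scored features (training statistics), k=4; distance ties break toward
the earlier training index and vote ties toward the positive class,
favoring recall on welfare events. A random-forest comparison is
available behind the same interface via scikit-learn; K-NN is the
bespoke path.

**Benchmark study design.** The classification benchmark simulates 60
days with an enriched lameness incidence (20% of cows) because the 5%
pipeline default yields only ~28 positive cow-days — far too few for a
stable held-out confusion matrix. Negative cow-days are down-sampled to
3 : 1 against positives (class prevalence in real herds is unknown and
any choice must be explicit). Results on this synthetic benchmark are
labeled as such everywhere; they are not comparable to accuracies
reported on proprietary farm data.

## Numerical conventions and degenerate inputs

* One master seed; per-stage seeds derive from it via named
  `SeedSequence` children, so stages re-run in isolation bit-identically.
* Activity quantization: integer steps, lying to 4 decimals, swaps as
  integer daily totals /24 — the stream round-trip is then exact (the
  aggregator rounds reconstructed lying hours at 6 decimals to absorb
  float summation error).
* Simulated activities are clipped to their physical ranges
  (steps ≥ 0, lying ∈ [0, 24], swaps ≥ 0) after event modification.
* Empty days, empty windows, zero `bytes_in`, single-class training
  sets, partial cow-days and date mismatches all raise errors naming
  the offending entity; the pipeline skips classification (reporting an
  empty evaluation) when a run plants no anomalous cow-days.
* Percentage rounding is half-up (`floor(x + 0.5)`), not banker's.

## Problem sizes

The test suite and acceptance script run the full herd (147 cows) at
14–60 days: 14 days for structure recovery, 40 for alert calibration,
60 for classification and the end-to-end pipeline (~2.1 M sensor
messages), sizes at which every stochastic property in the suite is
stable across seeds while the whole stack stays fast.

## Known limitations

* The generator's independence assumptions (no autocorrelation, no herd
  social effects, i.i.d. daily noise) make recovery properties cleaner
  than field data would allow.
* Heat, calving and lameness magnitudes are scenario parameters, not
  estimates; detection thresholds are calibrated to the simulator and
  are a starting point, not a validated clinical rule.
* The telemetry model abstracts away transport entirely (no broker,
  no QoS handshakes, no gateway storage limit).
* Cluster assignment assumes the normal cluster is the (weighted)
  center of the herd; herds whose cluster mix is far from the default
  may need τ or the offsets revisited.
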