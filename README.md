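# herdsense

Behavioral analytics for dairy-herd activity monitoring.

Modern dairy farms fit cows with pedometers that report step counts, lying
time and lying↔standing transitions ("swaps") every few minutes to an
on-farm gateway. From those three signals alone a farmer can be alerted to
the events that matter most: **oestrus (heat)** — a ~18-hour fertile window
in a ~21-day cycle, marked by a sudden step spike, that must be caught in
time for insemination; **lameness and illness** — a decline in steps and
rise in lying that precedes visible symptoms by days; and **calving** —
seclusion and increased lying as a pregnant cow nears term.

`herdsense` is a tested, reusable implementation of that analytics stack
for researchers and engineers in precision livestock farming. Because no
public herd dataset of this kind exists, the package ships a first-class
synthetic herd simulator with known latent structure and planted welfare
events, so every stage is verifiable end to end.

## The method

For cow *c* on a given day, let *Hₘ* be the herd mean of an activity and
*Cₐ* the cow's value. The core statistic is the per-activity absolute
deviation from the herd mean,

```
C_AD = |Hm − Ca|
```

computed daily for steps, lying hours and swaps/hour. A **best-of-three**
directional vote over window-mean deviations assigns each cow to a
behavioral cluster: *active* (above the herd mean in steps and swaps,
below in lying), *dormant* (the mirror), or *normal* (near the mean on a
majority of activities), where "near" means within τ·MAD of the daily
signed deviations. On top of the cluster trajectory sit the alert rules
(step-spike heat detection against a per-cow rolling median; sudden
active/normal→dormant migrations; dormant activity drops; pre-calving
lying rises) and a from-scratch K-nearest-neighbors classifier (k=4,
z-scored Euclidean) that labels cow-days *irregular* vs *regular* and is
scored by sensitivity, specificity, accuracy and detection lead time.

The telemetry layer models the on-farm gateway: 6-minute, 299-byte sensor
messages (≈70 KB/sensor/day) aggregated to daily records before
forwarding — an ~84% reduction in data streamed off-farm — with a
store-and-forward contract under outages: cloud outages of any length
delay but never lose data; sensor-side retention covers gateway outages
up to 12 h.

## Worked example

```python
import herdsense as hs

cfg = hs.HerdConfig(seed=7)                  # 147 cows, reference age mix
roster = hs.generate_herd(cfg)
activity, events = hs.simulate_activity(roster, 14, cfg)

profiles = hs.compute_deviation_table(activity)
dispersion = hs.compute_herd_dispersion(profiles)
dates = sorted(profiles["date"].unique())
assignments = hs.assign_clusters(profiles, dispersion, (dates[0], dates[-1]))
table = hs.cross_tabulate(assignments, roster)
print("cluster totals:", table.totals)
print("herd percentages:", {f"{g}/{c}": p for (g, c), p in sorted(table.pct_of_herd.items())})

alerts = hs.detect_heat(activity)
print(f"heat alerts: {len(alerts)} "
      f"(planted oestrus events: {sum(t.kind == 'oestrus' for t in events)})")

report = hs.compute_volume_report(int(10.1 * 1024**2), int(1.62 * 1024**2))
print(report.render())
```

prints

```
cluster totals: {'active': 54, 'normal': 83, 'dormant': 10}
herd percentages: {'old/active': 7, 'old/dormant': 6, 'old/normal': 12, 'young/active': 30, 'young/dormant': 1, 'young/normal': 45}
heat alerts: 37 (planted oestrus events: 83)
10.10 MB in -> 1.62 MB out (84% reduction)
```

The clustering recovers the planted 54/83/10 active/normal/dormant
structure exactly, and the herd percentages by age group (young 2–5 y,
old 6–12 y) follow. The 37 heat alerts cover the planted oestrus windows
that have enough prior history for a rolling baseline (the first week of
a cow's record cannot be scored). The volume report shows the
gateway-side reduction for one day of a 147-sensor farm.

A CLI wraps the same stages:

```bash
herdsense simulate --days 60 --seed 7 --out activity.csv
herdsense profile --activity activity.csv --window 7 --out assignments.csv
herdsense alerts --activity activity.csv --out alerts.jsonl
herdsense volume-report --in-bytes 10590617 --out-bytes 1698693
herdsense run --seed 7 --out runs/demo        # end-to-end pipeline
```

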