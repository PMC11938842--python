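# chamberqc

Quality control and stability assessment for sensor streams from
controlled-environment agriculture (CEA) chambers.

Air temperature in a controlled chamber oscillates on a fixed day/night
photoperiod, so a robust diurnal profile — the per-(hour:minute) **median**
of all observations in a trial, 1440 slots — captures the "ideal" daily
pattern. `chamberqc` uses this profile three ways:

1. **Imputation** — missing minutes are replaced by the profile value at the
   matching time-of-day slot ("coalescing").
2. **Decomposition** — subtracting the tiled profile from the coalesced
   series de-seasonalizes it directly (the *alternative* route); a classical
   additive decomposition (centered moving average + seasonal figure) is
   kept as a comparator.
3. **Outlier detection** — residuals are z-scored per sensor/trial and
   flagged at a two-sided significance level (default α = 0.001,
   |z| > 3.29).

Flagged outlier magnitudes feed two downstream analyses: candidate
distribution fitting (normal / lognormal / gamma / weibull / logistic /
cauchy, ranked by AIC/BIC; MLE or Cramér–von Mises minimum-distance), and a
stability regression of log|z| against the cumulative agricultural-operations
covariate (person-minutes derived from door/person event logs) with sensor
main effects and interactions.

A fully seeded synthetic chamber simulator (square-wave setpoints with
exponential transition lag, per-sensor bias/noise, block missingness, and six
planted-anomaly kinds with ground-truth labels) makes every stage testable
without external data.

## Library quick start

```python
import chamberqc as cq

# simulate one 28-day trial with a couple of planted anomalies
cfg = cq.SimConfig(
    trials=[cq.TrialConfig("T1", 30, 24, 16.5, 7.5, ("2021-03-01", "2021-03-29"))],
    sensors=[cq.SensorSpec("LC_Canopy_1", noise_sd=0.2)],
    anomalies=[cq.AnomalyEvent("power_surge_spike", "2021-03-10T12:00", 1, 3.0)],
    seed=7,
)
sim = cq.simulate_chamber(cfg)

s = sim.series[0]
profile = cq.build_surrogate(s)                 # 1440-slot median profile
part = cq.coalesce(s, profile)                  # gap-free series
alt = cq.alt_decompose(part, profile)           # residuals via profile subtraction
table = cq.zscore_outliers(alt)                 # flags at |z| > 3.29
metrics = cq.labels_to_truth(
    sim.labels, table.rows.assign(sensor_id=s.sensor_id)
)
print(table.outlier_count, metrics.recall_overall)
```

## CLI

```bash
chamberqc simulate --seed 7 -o data/            # synthetic sensor/event CSVs
chamberqc decompose data/sensors.csv -o out/    # tidy decomposition CSV
chamberqc outliers  data/sensors.csv -o out/ --alpha 0.001
chamberqc fitdist   out/outliers.csv -o out/ --method mle
chamberqc agrops    data/events.csv  -o out/ --window 2021-03-01 2021-03-08
chamberqc regress   joined.csv -o out/ --per-trial
chamberqc report    -c config.yaml              # full pipeline bundle
```

`report` runs everything from a YAML config (paths, trial plan, α, Agr.Ops
weights, fit method) and writes `raw_summary.csv`, `summary.csv`,
`decomposition.csv`, `outliers.csv`, `distfit.csv`, `agrops.csv`,
`regression.csv` plus a `manifest.json` with the config hash; reruns are
byte-identical.

File formats are plain CSV: sensor logs `timestamp,sensor_id,value_c`
(ISO-8601), event logs `timestamp,channel,state` with channels
`door`/`person_1..3` and binary states.

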