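# wanderlens

Ambient smart-home locomotion mining for unobtrusive cognitive screening.

Smart homes instrumented with passive infrared (PIR) motion sensors, door
contacts and tagged everyday objects record a resident's movement without
cameras or wearables. Indoor travel patterns carry diagnostic signal: in the
Martino-Saltzman taxonomy, cognitively healthy (CH) residents mostly walk
*direct* paths, while *random*, *pacing* (back-and-forth) and *lapping*
(repeated loops) travel are characteristic of people with dementia (PwD).
`wanderlens` turns raw sensor event logs into a per-person screening
hypothesis:

```
event log ──► position records ──► noise filter (v ≤ 15 m/s, d ≤ 5 m)
          ──► locomotion episodes (sensing gap > Ts ends an episode)
          ──► annotated trajectory images (speed-shaded path, traversal
              thickness, turn/stationarity/sharp-angle/interaction markers)
          ──► 15 connected-region features + K-bin visual-word histogram
          ──► SMOTE-balanced classifier (NB / kNN / DT / SVM / NN),
              leave-one-person-out (LOPO) cross-validation
          ──► per-person diagnosis: ltp = argmax_c |{c ∈ {c₁,…,c_m}}|
```

Per class, precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R);
macro averages treat both classes equally (the imbalance-robust headline
number), weighted averages are support-weighted. SMOTE oversamples the
minority class with convex combinations `a + λ(b − a)` of a minority point
and one of its k = 5 nearest minority neighbours, inside each training fold
only.

A built-in synthetic smart home (52-PIR grid at 1 m resolution, disk-model
sensing, all four movement patterns) generates labeled CASAS-dialect event
streams, so the entire pipeline is testable without external data.

## Worked example

Simulate a 50-subject cohort (40 CH, 10 PwD) and run the full pipeline with
the default RBF-SVM (C = 0.7), SMOTE, Ts = 60 s and a 50-word vocabulary:

```
$ wanderlens simulate --out cohort --seed 1 --n-ch 40 --n-pwd 10
wrote 50 subject streams to cohort

$ wanderlens run --events-dir cohort --positions cohort/positions.csv \
    --manifest cohort/manifest.csv --out results --seed 1
```

which reports (abridged):

```json
{
  "short_term": {"macro": {"precision": 0.8086, "recall": 0.8702, "f1": 0.8328}},
  "long_term":  {"macro": {"precision": 0.9167, "recall": 0.9750, "f1": 0.9417}}
}
```

Read: episode-level screening separates CH from PwD walks at macro-F1 0.83
across 539 episodes, and the per-person majority vote diagnoses 48 of the 50
subjects correctly (accuracy 0.96, long-term macro-F1 0.94). `results/`
also contains the feature matrix (`features.csv`), per-episode predictions
(`predictions.csv`), per-subject diagnoses with vote counts
(`diagnoses.csv`) and the full metrics JSON with a provenance stamp.

Every stage is also available on its own (`ingest`, `segment`, `encode`,
`features`, `evaluate`, `assess`), reading and writing plain CSV/JSON/PNG so
stages can be inspected or replaced in isolation. Event logs are
whitespace-delimited `[date] time sensor_id value` lines (CASAS dialect);
the position table is a `sensor_id,x,y` CSV in meters. Thresholds, palette,
canvas, vocabulary size and model choice live in a validated YAML config
(`--config`), and every entry point takes `--seed`.

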