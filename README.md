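# movesoc

Movement, social opportunity and mixed-model pipeline for group-living
animals, with a synthetic troop generator for end-to-end validation.

The package turns four per-individual data streams — high-resolution GPS
fixes, faecal thyroid hormone (fT3) samples, accelerometer-classified
grooming bouts, and individual metadata — into a chained mixed-model
analysis of how daily energy availability relates to movement, how movement
relates to close-proximity "social opportunity" events, and how those
opportunities relate to grooming given and received.

## What it computes

* **Movement metrics** (`movesoc.trajectory`): per individual-day total
  travel distance (all habitats) and medians of step length, sinuosity
  (corrected index `2·[p(1+c)/(1−c)]^(−1/2)`) and residence time (time
  inside a disc of the day's mean step length, allowing excursions up to a
  5-min cut-off), computed on 60-s resampled, natural-habitat path segments
  of ≥5 consecutive fixes.
* **Social opportunities** (`movesoc.proximity`): dyadic events where two
  collared individuals are ≤2 m apart (boundary inclusive), with
  re-contacts within 2 s merged; daily per-individual frequencies with an
  active-collar filter (≥10 collars by default).
* **Hormone covariates** (`movesoc.hormones`): daily means, a 48-h
  excretion lag (behaviour day *d* ↔ sample day *d+2*), and the
  within-/between-individual split into individual mean and mean-centred
  deviation. Plus rank standardisation to [0, 1] and Spearman validation
  utilities.
* **Grooming totals** (`movesoc.grooming`): sunrise-to-sunset minutes of
  grooming given/received per day (NOAA solar position, zenith 90.833°).
* **Model suite** (`movesoc.models`, `movesoc.lmm`): seven linear mixed
  models with log/sqrt response transforms, z-scored predictors, crossed
  random intercepts (individual, date), correlated random slopes,
  REML coefficient tables, ML likelihood-ratio tests against control-only
  nulls, and VIF collinearity checks. The LMM engine is written in-house
  (profiled REML/ML, Woodbury likelihood) and is validated against `lme4`
  in the test suite.
* **Synthetic generator** (`movesoc.simulate`): an agent-based cohesive
  troop with a latent daily energy state driving a two-state
  (area-restricted search vs transit) movement process, emergent
  shared-patch encounters, and opportunity-driven grooming — all structural
  coefficients known, so the pipeline supports parameter-recovery and
  type-I-error experiments.

## CLI

All commands are under one entry point:

```bash
movesoc simulate  --config gen.yaml --seed 1 --out-dir data/   # synthetic streams
movesoc metrics   --gps data/gps.csv --interval 60 --cutoff-min 5 --out metrics.csv
movesoc proximity --gps data/gps.csv --threshold 2 --merge-gap 2 \
                  --min-collars 10 --out-events events.csv --out-counts counts.csv
movesoc groom     --bouts data/grooming_bouts.csv --out grooming.csv
movesoc fit       --config fit.yaml --out-dir fits/            # seven-model suite
movesoc recover   --replicates 50 --seed 1 --mode recovery --out report.json
```

`fit.yaml` names the input CSVs (`gps`, `hormones`, `bouts`, `metadata`)
and optional knobs (`lag_hours`, `threshold`, `merge_gap`, `min_collars`,
`ft3_interaction`). GPS tables may use either the geographic dialect
(`individual_id,timestamp,lon,lat,habitat`) or the planar one
(`individual_id,timestamp,x,y,habitat`); the dialect is auto-detected.

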