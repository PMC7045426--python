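# scaleimpute

Benchmarking strategies for handling missing items in psychometric
questionnaires.

When a respondent skips individual items of a Likert-type scale, the whole
total score is lost unless the gaps are handled. `scaleimpute` is a small,
fully reproducible pipeline for studying how much each common remedy costs:
it generates synthetic questionnaire populations with realistic covariate
structure, deliberately amputes them under a missing-at-random (MAR)
mechanism at calibrated item-level rates, repairs them with four strategies —

1. **complete-case deletion** — drop every respondent with any missing item,
2. **mode imputation** — fill each cell with its item's most frequent
   observed value,
3. **random hot-deck** — fill each cell with the value of a random donor
   from the same covariate-defined donor class,
4. **multiple imputation (MI)** — chained equations with predictive-mean
   matching, m completed datasets combined by Rubin's rules —

and scores each strategy against the complete data. Writing `y_ij` for a
summary statistic (total-score mean, SD, or its correlation with a
covariate) computed after method *j* in replication *i*, and `y_i0` for its
complete-data value, the benchmark reports per (method × rate) cell:

- absolute deviation `|y_ij − y_i0|` (mean ± SD over replications),
- `RMSE = sqrt( Σ_i (y_ij − y_i0)² / n )`,
- signed average relative error `Σ_i ((y_i0 − y_ij)/y_i0) / n`.

A second, survey-analysis tier runs the analyses a practitioner would
actually publish — group *t*/*F* tests of the total score and a multiple
logistic regression on the dichotomized score (e.g. self-esteem ≥ 30 vs
< 30) — identically on complete and imputed data, and tabulates the deltas,
including Rubin-pooled odds ratios for the MI arm.

## Worked example

```python
from scaleimpute import get_preset, run_benchmark

preset = get_preset("saq")          # 16-item scale, n=742 college students
data = preset.generate(seed=7)
records, table = run_benchmark(
    data, preset.covariates,
    rates=(0.05, 0.20), n_reps=10, master_seed=7,
    driver_slopes=dict(preset.mar_driver_slopes),
    donor_class_vars=preset.donor_class_vars, mi_m=10,
)
print(table[table.statistic == "mean"][["method", "rate", "abs_dev_mean", "rmse"]])
```

prints (see `examples/benchmark_methods.py`):

```
  method   rate  abs_dev_mean   rmse
deletion 0.0500        0.7843 0.8077
deletion 0.2000        1.8254 1.8920
 hotdeck 0.0500        0.0454 0.0543
 hotdeck 0.2000        0.1864 0.2012
      mi 0.0500        0.0290 0.0309
      mi 0.2000        0.0567 0.0637
    mode 0.0500        0.1442 0.1482
    mode 0.2000        0.5093 0.5225
```

Deletion biases the total-score mean worst (the MAR mechanism removes
low-scoring respondents preferentially, so the survivors mislead), mode
imputation is next, and hot-deck and MI stay within a few hundredths of a
point; every method's error grows with the missingness rate.

Three presets ship with the package: `rses` (10 items, 1–4, cutoff 30,
n=3513, total score calibrated to mean ≈ 28.2, SD ≈ 4.6), `saq` (16 items,
n=742) and `adl` (14 items, n=1242). `examples/` holds one short script per
capability: population generation, amputation + repair, the replicated
benchmark, and the validation battery.

## Command line

```bash
scaleimpute simulate --config run.yaml --seed 1 --out results/sim
scaleimpute validate --config run.yaml --out results/val
scaleimpute metrics  --records results/sim/benchmark.csv --out results/sim
```

`run.yaml` can be as small as `preset: saq`; every knob (rates,
replications, methods, MI settings, donor classes, MAR driver slopes,
master seed) has a declared default and round-trips through the file. Each
run writes a `manifest.json` with per-file checksums so reruns can be
verified byte for byte.

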