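# bedtherm

Unobtrusive estimation of the **distal skin temperature (DST)** during
sleep from a five-sensor temperature strip embedded just below a smart
bed's mattress surface.

Skin temperature is tightly coupled to sleep: the transition from
wakefulness to sleep is driven by a core-body-temperature decline that is
achieved by peripheral vasodilation, which raises distal (hand/foot/wrist)
skin temperature by roughly 1 °C and proximal (trunk) temperature by
roughly 0.5 °C. Measuring DST longitudinally normally requires wearables
or skin-attached sensors. `bedtherm` implements an estimator that needs
only the bed: per-minute strip temperatures T1(n)..T5(n) are sorted and
the top three values (the sensors most likely touching the body) feed a
two-stage regression

    X(n) = GBT(V1(n), V2(n), V3(n))            # gradient boosted tree
    Y(n) = RF(X(n), X(n−1), …, X(n−4))         # random forest on a
                                               # 5-minute rolling window

trained sequentially against a robust-LOWESS-smoothed wrist reference.
Accuracy is summarised per sleep session with Bland–Altman statistics
(bias, SD of differences, 95 % limits of agreement bias ± 1.96·SD_d) and
the coefficient of determination R², aggregated through **subject-blocked
five-fold cross-validation** (no participant contributes to both training
and validation). A lights-off verification compares grand-average change
curves of the estimated DST against an independently measured foot
temperature.

Because sleep recordings of this kind are not publicly available, the
package ships a **synthetic thermodata simulator** (multi-subject,
multi-night studies with sensor quantization, clock jitter, contact-
coupling variability, and null/negative/oscillation/bed-absence
artifacts) so the entire pipeline is buildable, testable and reproducible
from a seed alone.

Intended users: sleep researchers and biosignal engineers who want a
reference implementation of strip-based DST estimation, or a testbed for
preprocessing/validation choices around it.

## Worked example

```python
from bedtherm.simulate import default_study
from bedtherm.evaluate import preprocess_study, run_cv

fixture = default_study(seed=1)          # 20 subjects x 5 home nights (+ lab)
features = preprocess_study(fixture)     # minute features + 80 % quality gate
result = run_cv(features, k=5, seed=1)   # subject-blocked five-fold CV
print(result.fold_table().round(3))
print({k: round(v, 4) for k, v in result.grand_means.items()})
```

Output:

```
   fold   bias  lower_loa  upper_loa     r2
0     1 -0.027     -0.151      0.097  0.925
1     2 -0.021     -0.166      0.124  0.943
2     3  0.014     -0.129      0.156  0.914
3     4  0.019     -0.104      0.142  0.896
4     5  0.025     -0.131      0.181  0.882
{'bias': 0.0019, 'sd_d': 0.0704, 'lower_loa': -0.136, 'upper_loa': 0.1399, 'r2': 0.912}
```

Each row is one validation fold: `bias` is the mean reference-minus-
estimate difference (°C) averaged over the fold's sleep sessions,
`lower_loa`/`upper_loa` bound the interval expected to contain 95 % of
per-minute errors, and `r2` is the share of reference-DST variance the
estimate explains. On this calibrated synthetic study the estimator
recovers the reference with near-zero bias, limits of agreement well
inside ±1 °C and R² ≈ 0.9 in every fold — the machinery works; see
`docs/methods.md` for why synthetic accuracy does not transfer to real
mattresses.

The same pipeline is scriptable from the shell:

```bash
bedtherm simulate --subjects 4 --nights 3 --seed 7 --out run/
bedtherm cv --config config.yaml --out run/       # fold table CSV
bedtherm verify --config config.yaml --out run/   # change curves + Pearson r
```

## Layout

| module | role |
| --- | --- |
| `bedtherm.simulate` | synthetic physiology, streams, artifacts, study fixtures |
| `bedtherm.preprocess` | minute aggregation, quality flags, top-3 selection, LOWESS reference |
| `bedtherm.estimator` | two-stage model, sequential training, TPE-style tuning, persistence |
| `bedtherm.evaluate` | Bland–Altman/R², subject folds, CV, learning curves, change curves |
| `bedtherm.io` / `bedtherm.cli` | CSV/Parquet + YAML schema, run configs, command line |
| `bedtherm.datasets` | bundled printed study tables for worked examples |
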