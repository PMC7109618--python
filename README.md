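# trendsieve

Structural temporal pattern detection for predicting adverse events in
critical care, demonstrated on acute kidney injury (AKI).

More than half of ICU patients develop AKI, and most risk models feed a
classifier only the *last recorded value* of each vital sign or lab before
the prediction point, discarding the trajectory that led there. This
package implements the alternative: segment the first 48 hours of each
channel into fixed windows, fit a small family of curve shapes — constant,
straight, exponential, sinusoidal, triangular — to each window (**local
trends**) and to the series of per-window means (**global trends**), and
use the fitted parameters as classifier features. It is written for
clinical-informatics researchers who want to benchmark trend-based feature
extraction against the common baselines on their own cohorts, or on the
included synthetic ones.

## The method

Each series `Y(t)` is approximated by every family `f(t)` and scored with
the error function

```
E = Σ_t (Y(t) − Ŷ(t))²,
```

the best family winning by minimal `E` (ties to the simpler shape). Each
fit is summarized as four numbers `(a, b, c, index)` — the parameters and
the winning family's index 1–5. Constant and straight fits are closed-form
least squares; the nonlinear families are fitted by multi-start
Nelder–Mead simplex search. With `m` windows per channel this gives `4m`
local features, 4 global features, or `4m + 4` combined, per channel —
1700 features for 17 channels at the default 2 h windows.

Two baselines are included: the last recorded value, and a symbolic
pipeline in the KarmaLego style (SAX discretization into 4 symbols, mining
of time-interval-related patterns under the relations *before* /
*overlaps* / *contains* at 60% vertical support, mean-duration features).

AKI is labeled from serum creatinine by the AKIN criteria — a rise
≥ 0.3 mg/dL within 48 h, or ≥ 1.5× the (in-stay) baseline within 7 days —
and stays that die or reach AKI onset inside the 48 h horizon, or look like
end-stage renal disease on admission (creatinine > 4 mg/dL), are excluded.

The evaluation harness splits the cohort 30/70 (stratified), runs 20-fold
cross-validation with identical folds for every method, and compares the
arms in a 2×2 factorial (local × global features, symbolic control) with a
repeated-measures ANOVA over the paired per-fold accuracies.

## Worked example

MIMIC-class ICU data is access-restricted, so the example runs on a
synthetic cohort whose class signal lives in the trends (see
`docs/methods.md` for what the generator does and does not emulate):

```python
import warnings; warnings.filterwarnings("ignore")
from trendsieve import (SyntheticConfig, generate, label_cohort,
                        factorial_experiment)

cohort = label_cohort(generate(SyntheticConfig(n_patients=2000, seed=1)))
print(f"prevalence: {cohort.prevalence():.4f}")

result = factorial_experiment(
    cohort, seed=1, folds=20,
    methods=("last_value", "local", "global", "combined"),
)
print(result.mean_metric("accuracy").round(4).to_dict())
print("combined vs last value: p =",
      result.contrasts["combined_vs_last_value"]["p"])
```

Output:

```
prevalence: 0.5700
{'combined': 0.8036, 'global': 0.715, 'last_value': 0.545, 'local': 0.795}
combined vs last value: p = 1.11e-12
```

Reading it: 57% of the generated stays develop AKI, so always predicting
"AKI" scores 0.57 — which is all the last-value features manage (0.545),
because every engineered excursion returns to baseline before the
prediction point. Global trend fitting recovers the slow whole-series
drifts (0.715), local window fits add the short-horizon structure (0.795),
and their combination is best (0.804); the repeated-measures ANOVA puts
the combined-vs-last-value gap far below p = 0.01.

A command-line interface wraps the same pipeline
(`trendsieve generate / features / evaluate / sweep`); feature matrices are
written as CSV with an `aki` label column, cohorts as long-format CSV
(`patient_id,channel,time_hours,value`).

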