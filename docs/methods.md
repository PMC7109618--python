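# Methods

`trendsieve` predicts an adverse event — acute kidney injury (AKI) — from the
first 48 hours of multichannel ICU time series by *structural temporal
pattern detection*: fitting a small family of parametric curve shapes to the
data and using the fitted parameters as classifier features. This note
documents the model, its assumptions, the numerical choices, what the
synthetic cohorts do and do not emulate, and the known limitations.

## Outcome definition (AKIN creatinine criteria)

A stay is labeled AKI-positive when either creatinine criterion fires:

* **Absolute rise** — two measurements `t1 < t2` with `t2 − t1 ≤ 48 h` and
  `v2 − v1 ≥ 0.3 mg/dL`. By default every sample pair is examined
  (`pairing="pairwise"`); `"consecutive"` restricts to adjacent samples.
* **Relative rise** — a measurement at least `1.5×` the baseline within
  7 days (168 h) of the baseline. Creatinine before ICU admission is
  unavailable, so the baseline is the in-stay minimum; we use the *running*
  minimum, anchored at the time it was first attained, so a sample is only
  compared against baselines that precede it. Both the window and the anchor
  rule are parameters of `label_aki`.

Onset is the earliest qualifying sample. Comparisons carry a `1e-9`
tolerance because decimal thresholds (0.3, 1.5×) are not exactly
representable in binary floating point and exact-at-threshold measurements
must flag.

Exclusions mirror the intended cohort: death before the 48 h horizon, AKI
onset within the horizon, and an end-stage-renal-disease proxy (admission
creatinine > 4 mg/dL). One reason is logged per excluded stay, in that
order of precedence; the filter is idempotent.

## Windowing and trend representations

The horizon (48 h) is partitioned into `m = horizon/width` half-open windows
`[i·w, (i+1)·w)`; a timestamp exactly at the horizon joins the last window.
Supported widths are 1, 2, 4, 6 and 8 h (48, 24, 12, 8, 6 windows); 2 h is
the default. Four per-patient representations are built per channel:

* **last_value** — the last recorded value before the horizon (1 feature).
* **local** — each window's best structure fit `(a, b, c, index)`
  (`4·m` features). Local time is measured from the window start so fits
  are translation-comparable across windows.
* **global** — the best structure fit to the piecewise aggregate
  approximation (PAA; per-window means) against window index (4 features).
* **combined** — local followed by global (`4·m + 4` features; 1700 columns
  for 17 channels at m = 24).

Missing data never changes vector lengths. Empty windows are imputed at the
window-mean level (default: carry the last observed mean forward, first
observed mean backward across leading gaps; linear interpolation is the
alternative policy) and contribute constant fits at the imputed mean. A
channel absent from a patient falls back to an all-constant fit at the
training-cohort median, with a warning. We deliberately impute at the mean
level rather than inventing samples: carried means preserve trend shape
without fabricating within-window variance.

## Structure detectors

Five families, scored by the sum of squared residuals
`E = Σ (Y(t) − Ŷ(t))²` and selected by minimum `E` with ties broken toward
the lower (simpler) index:

| index | family      | form                                     |
|-------|-------------|------------------------------------------|
| 1     | constant    | `a`                                      |
| 2     | straight    | `a·t + b`                                |
| 3     | exponential | `a·e^{b·t} + c`                          |
| 4     | sinusoidal  | `a·sin(b·t) + c`                         |
| 5     | triangular  | `a − b·|t − c|`, clamped below at min(Y) |

Constant and straight use closed-form least squares. Single-sample series
always use the constant detector; two-sample series admit only the
closed-form families. Degenerate straight fits (all times equal) fall back
to slope zero through the mean.

The three nonlinear families are fitted by multi-start Nelder–Mead simplex
search. Starting points are *profiled*: the nonlinear parameter (rate `b`,
frequency `b`, or peak location `c`) is scanned on a coarse grid — a signed
log-spaced rate grid; a frequency grid up to the Nyquist limit plus the
dominant FFT bin for uniformly sampled series; the sample positions and
midpoints for the peak — and the two remaining parameters, in which the
model is linear, are solved by normal equations for every grid point at
once. The best five starts are kept, all are evaluated with the true
objective (so the returned error never exceeds any start's error), and the
best is polished by a simplex run (default 150 iterations, parameter/value
tolerance 1e-8). With profiled starts the polish converges in far fewer
steps than a cold-started search; noiseless signals from each family are
recovered with the correct index in 100% and with < 1e-3 relative parameter
error in ≈ 98–100% of seeded draws, and the fit dominates a 20×20×20
brute-force grid search. Because selection is an argmin, any strictly
increasing transform of `E` (e.g. RMSE) selects the same family.

Since `E ≥ 0` and the constant family is always in the candidate set, the
selected error never exceeds the constant fit's error. Non-convergence
within the iteration cap returns the best-seen parameters with a warning.

## Symbolic baseline (KLS-style TIRP mining)

The control pipeline abstracts each channel's window means into symbols and
mines time-interval-related patterns (TIRPs):

* **Discretization** — SAX (default): z-normalize per channel with
  *training-cohort* statistics, cut at standard-normal quantiles into 4
  equal-probability bins; zero-spread series map to the middle symbol
  `(alphabet+1)//2`. EWD: equal-width bins between the training min/max,
  top bin closed. Runs of equal symbols merge into maximal intervals.
* **Relations** — three abstractions of Allen's relations between
  canonically ordered intervals (start, end, channel lexicographic):
  `before` (gap > ε), `contains`, else `overlaps` (which absorbs meets,
  starts, finishes, equal). ε = 0 by default.
* **Mining** — level-wise KarmaLego-style search: exhaustive size-2
  enumeration, then extension of frequent patterns only, pruning on the
  anti-monotonicity of vertical support (fraction of patients containing an
  instance; threshold 60%), up to size 3 by default. Pair and triple keys
  are packed into integers so candidate generation and support counting are
  vectorized; anti-monotonicity is asserted during mining. The miner is
  validated against exhaustive enumeration on randomized toy databases.
* **Features** — one column per frequent TIRP: the mean, over all instances
  in the patient, of (last interval end − first interval start); 0 when
  absent. All instances are counted, not just the first. A fast
  integer-coded matcher produces the matrix; it is tested for exact
  equality against the straightforward per-pattern matcher.

Discretization statistics and the frequent set are learned inside each
training fold and applied to the test fold, so nothing leaks. If no pattern
survives mining, the transformer emits a single zero column so a downstream
classifier degrades to the majority class.

## Evaluation harness

30% of the cohort (stratified, seeded) is reserved as a development set;
the remainder is evaluated with stratified 20-fold cross-validation. Split
arithmetic rounds the total to the nearest integer, then the positive
stratum to the nearest integer of proportion × total — for a 22,542-patient
cohort at 57.00% prevalence this yields 6,763 development (3,855 positive)
and 15,779 modeling patients. All methods are scored on *identical* fold
assignments, making per-fold metrics paired observations. Metrics:
accuracy (primary), positive-class F-measure at the default 0.5 vote
threshold, and AUC from out-of-fold scores.

The comparison is a 2×2 within-subject factorial — local features on/off ×
global features on/off — with the symbolic pipeline as the control cell and
folds as subjects. A one-way repeated-measures ANOVA (method × fold)
partitions variance into method, subject and residual
(`F = MS_method / MS_residual`, df `(k−1, (k−1)(n−1))`); the factorial
variant tests each main effect against its own effect-by-subject
interaction. Zero between-method variance returns `F = 0, p = 1` by
convention. Both are validated against an independent sum-of-squares oracle
and against `statsmodels` `AnovaRM`.

The default classifier is a seeded random forest with 200 trees
(`n_jobs=1`): accuracy is flat in the tree count well below this on our
matrices, and the smaller ensemble keeps the five-arm factorial fast. Any
scikit-learn classifier can be plugged in. Feature matrices are fed to the
classifier unscaled — trees are invariant to monotone per-feature
transforms — so users plugging in scale-sensitive models should add their
own standardization step.

Structural feature matrices are deterministic given the cohort, so they are
computed once per experiment and shared across folds; the combined matrix
is assembled from the cached local and global blocks. The symbolic
pipeline, whose fit is data-dependent, re-fits per fold.

## Synthetic cohorts

Real critical-care data is access-restricted, so the generator emulates the
statistical features the method cares about:

* 48 h stays over 17 channels; hourly sampling for monitored channels
  (vitals, blood-gas bicarbonate), 6-hourly for labs; whole windows knocked
  out with probability 0.1; ~57% positive prevalence (positives are exactly
  `round(prevalence·n)`).
* Noise is an Ornstein–Uhlenbeck physiological drift (timescale 12 h, 75%
  of the variance) plus white measurement noise — clinical series are
  autocorrelated, and this also keeps symbolic interval counts realistic.
* Creatinine is engineered per class: positives stay flat inside the
  horizon and climb 0.05 mg/dL/h afterwards (AKI onset after hour 48, so no
  positive is excluded by the horizon filter); negatives stay flat with
  ±0.02 jitter. AKIN labeling reproduces the intended class for every
  record.
* The class signal is trend-borne by design, layered so each representation
  has a component only it can see:
  - *heart rate*: a window-aligned zig-zag with zero window means, faded to
    zero near the horizon — visible only to local (within-window) slopes;
  - *blood urea nitrogen*: a broad triangular excursion with a per-patient
    peak time, returning to baseline before the horizon — visible to both
    local and global trends, not to the last value;
  - *bicarbonate and temperature*: low-amplitude tents spanning the whole
    horizon with jittered apex, drawn as closely spaced sample pairs
    (panel-style collection). Within-window slopes are then pure
    measurement noise and no single window mean is reliable, but the
    whole-series triangular/sinusoidal fit aggregates all windows like a
    matched filter — the component only global trends capture.

  All excursions vanish at the prediction point, so the last recorded value
  carries (almost) no class information and that baseline converges to the
  majority-class rate.

What the generator does **not** emulate: real marginal distributions,
cross-channel correlation, treatment effects, informative missingness, or
channel-specific measurement artifacts. Passing tests on these cohorts
demonstrates that the pipeline extracts the kinds of structure it claims
to extract — not that it attains any particular accuracy on real ICU data.

The 12-patient `fixture_small()` micro-cohort is hand-written (single-sample
windows, empty windows, exact lines, a triangular pulse, one patient per
exclusion rule) with hand-computed labels shipped alongside, and anchors
the labeling and exclusion tests.

## Problem sizes

The qualitative replication runs on a 2,000-patient cohort (1,400 modeling
after the 30/70 split) with 20-fold CV for the four structural/last-value
arms. The symbolic control arm re-mines per fold, which is the most
expensive step, so the factorial with the symbolic control cell runs on a
500-patient cohort; both sizes are package choices recorded here and in the
acceptance script.

## Known limitations

* The triangular clamp (floor at the series minimum) makes that family's
  prediction depend on the observed values, a pragmatic regularization of
  an otherwise unbounded descent.
* Family selection on low-signal series is noisy — flexible families can
  chase noise — so fitted parameters are meaningful mainly conditional on
  the selected index; the ordinal index is emitted as-is (an optional
  one-hot encoding exists for classifiers that cannot exploit ordinals).
* The 1.5× AKIN criterion's time anchor is under-specified clinically;
  the running-minimum rule is one defensible reading and is configurable.
* Vertical support counts patient presence, not instance counts; mean
  duration is the only TIRP representation implemented.
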