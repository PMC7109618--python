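"""Evaluation harness: stratified splitting, paired k-fold CV over the
factorial method set, repeated-measures ANOVA, and the window-size sweep.

The design mirrors a 2x2 within-subject factorial: local structural
features and global structural features are the two factors, the symbolic
TIRP pipeline is the control cell, and cross-validation folds are the
subjects.  Every method is evaluated on *identical* fold assignments so the
per-fold accuracies are paired observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline

from .cohort import Cohort, apply_exclusions, label_cohort
from .features import TrendFeaturizer
from .symbolic import TIRPFeaturizer
from .windowing import SUPPORTED_WIDTHS, WindowGrid, WindowingError

METHODS = ("last_value", "symbolic", "local", "global", "combined")

#: Factor coding of the 2x2 factorial cells (local on/off, global on/off).
FACTORIAL_CELLS = {
    "symbolic": (0, 0),
    "local": (1, 0),
    "global": (0, 1),
    "combined": (1, 1),
}


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class SplitPlan:
    """Development/modeling split and CV settings."""

    dev_fraction: float = 0.30
    folds: int = 20
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.dev_fraction < 1:
            raise EvaluationError("dev_fraction must be in (0, 1)")
        if self.folds < 2:
            raise EvaluationError("folds must be >= 2")


@dataclass
class EvalResult:
    """Per-fold, per-method metrics plus the ANOVA summaries."""

    table: pd.DataFrame  # columns: method, fold, accuracy, f1, auc
    anova: dict = field(default_factory=dict)
    factorial: dict = field(default_factory=dict)
    contrasts: dict = field(default_factory=dict)

    def mean_metric(self, metric: str = "accuracy") -> pd.Series:
        return self.table.groupby("method")[metric].mean()

    def wide(self, metric: str = "accuracy") -> pd.DataFrame:
        return self.table.pivot(index="fold", columns="method", values=metric)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_sizes(n_total: int, n_pos: int, dev_fraction: float) -> dict[str, int]:
    """Stratified split arithmetic: totals to the nearest integer, then the
    positive stratum to the nearest integer of proportion x total."""
    dev_total = _round_half_up(dev_fraction * n_total)
    dev_pos = _round_half_up(n_pos / n_total * dev_total)
    return {
        "development": dev_total,
        "development_positive": dev_pos,
        "modeling": n_total - dev_total,
        "modeling_positive": n_pos - dev_pos,
    }


def stratified_split(cohort: Cohort, plan: SplitPlan) -> tuple[Cohort, Cohort]:
    """Random, stratified development/modeling partition (disjoint, exhaustive)."""
    y = cohort.labels()
    if y.min() == y.max():
        raise EvaluationError("both classes must be present for a stratified split")
    sizes = split_sizes(len(cohort), int(y.sum()), plan.dev_fraction)
    rng = np.random.default_rng(plan.seed)
    pos = rng.permutation(np.flatnonzero(y == 1))
    neg = rng.permutation(np.flatnonzero(y == 0))
    dev_idx = set(pos[: sizes["development_positive"]]) | set(
        neg[: sizes["development"] - sizes["development_positive"]]
    )
    dev = [cohort.records[i] for i in sorted(dev_idx)]
    model = [cohort.records[i] for i in range(len(cohort)) if i not in dev_idx]
    return Cohort(dev, horizon=cohort.horizon), Cohort(model, horizon=cohort.horizon)


def default_classifier(seed: int = 0, n_estimators: int = 200) -> RandomForestClassifier:
    """The reference classifier: a seeded random forest.

    200 trees: the out-of-fold accuracy of a random forest is flat in the
    tree count well below this on our feature matrices, and the smaller
    ensemble keeps the 20-fold factorial comparison fast.
    """
    return RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)


def make_folds(y: np.ndarray, folds: int, seed: int, stratified: bool = True):
    """One fold assignment, reused across methods (paired design)."""
    if stratified:
        counts = np.bincount(y)
        if counts.min() < folds:
            raise EvaluationError(
                f"need >= {folds} examples of each class, got {counts.tolist()}"
            )
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros_like(y), y))


def _scores(model, X_test) -> np.ndarray | None:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X_test)[:, 1]
    if hasattr(model, "decision_function"):
        return model.decision_function(X_test)
    return None


def crossval(X, y: np.ndarray, estimator, folds=20, seed: int = 0, splits=None) -> pd.DataFrame:
    """Per-fold accuracy, positive-class F-measure and AUC.

    ``X`` may be a matrix or a list of patient records when ``estimator`` is
    a pipeline starting with a featurizer.  ``splits`` overrides the fold
    assignment (to pair methods)."""
    y = np.asarray(y, dtype=int)
    if splits is None:
        splits = make_folds(y, folds, seed)
    is_frame = isinstance(X, pd.DataFrame)
    rows = []
    for k, (tr, te) in enumerate(splits):
        if is_frame:
            X_tr, X_te = X.iloc[tr], X.iloc[te]
        elif isinstance(X, np.ndarray):
            X_tr, X_te = X[tr], X[te]
        else:
            X_tr = [X[i] for i in tr]
            X_te = [X[i] for i in te]
        model = clone(estimator)
        model.fit(X_tr, y[tr])
        pred = model.predict(X_te)
        score = _scores(model, X_te)
        auc = np.nan
        if score is not None and len(np.unique(y[te])) == 2:
            auc = roc_auc_score(y[te], score)
        rows.append(
            {
                "fold": k,
                "accuracy": accuracy_score(y[te], pred),
                "f1": f1_score(y[te], pred, pos_label=1, zero_division=0),
                "auc": auc,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------


def rm_anova(wide: pd.DataFrame) -> dict:
    """One-way repeated-measures ANOVA (rows: subjects/folds, cols: methods).

    Partitions variance into method, subject and residual; F is
    MS_method / MS_residual with (k-1, (k-1)(n-1)) degrees of freedom.
    With zero between-method variance the effect is nil: F = 0, p = 1.
    """
    if wide.isna().any().any():
        raise EvaluationError("rm_anova requires a complete, balanced table")
    Y = wide.to_numpy(dtype=float)
    n, k = Y.shape
    if n < 2 or k < 2:
        raise EvaluationError("rm_anova needs >= 2 subjects and >= 2 conditions")
    grand = Y.mean()
    ss_method = n * float(((Y.mean(axis=0) - grand) ** 2).sum())
    ss_subject = k * float(((Y.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((Y - grand) ** 2).sum())
    ss_resid = max(ss_total - ss_method - ss_subject, 0.0)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_method = ss_method / df1
    ms_resid = ss_resid / df2
    if ms_method <= 1e-300:
        F, p = 0.0, 1.0
    elif ms_resid <= 1e-300:
        F, p = np.inf, 0.0
    else:
        F = ms_method / ms_resid
        p = float(f_dist.sf(F, df1, df2))
    return {
        "F": float(F),
        "p": float(p),
        "df1": df1,
        "df2": df2,
        "ss_method": ss_method,
        "ss_subject": ss_subject,
        "ss_residual": ss_resid,
    }


def rm_anova_factorial(wide: pd.DataFrame, cells: dict[str, tuple[int, int]] | None = None) -> dict:
    """2x2 within-subject factorial ANOVA over the four factorial cells.

    ``wide`` has one column per method; ``cells`` maps method name to its
    (local, global) coding.  Each effect is tested against its own
    effect-by-subject interaction, the standard repeated-measures error term.
    """
    cells = cells or FACTORIAL_CELLS
    missing = [mth for mth in cells if mth not in wide.columns]
    if missing:
        raise EvaluationError(f"factorial table is missing cells: {missing}")
    # Y[subject, a, b] with a = local level, b = global level
    n = len(wide)
    Y = np.zeros((n, 2, 2))
    for mth, (a, b) in cells.items():
        Y[:, a, b] = wide[mth].to_numpy(dtype=float)
    grand = Y.mean()
    mean_a = Y.mean(axis=(0, 2))  # per local level
    mean_b = Y.mean(axis=(0, 1))  # per global level
    mean_ab = Y.mean(axis=0)
    mean_s = Y.mean(axis=(1, 2))
    mean_sa = Y.mean(axis=2)
    mean_sb = Y.mean(axis=1)

    out: dict = {}

    def _effect(name: str, ss_eff: float, ss_err: float, df1: int, dferr: int) -> None:
        ms_eff = ss_eff / df1
        ms_err = ss_err / dferr
        if ms_eff <= 1e-300:
            F, p = 0.0, 1.0
        elif ms_err <= 1e-300:
            F, p = np.inf, 0.0
        else:
            F = ms_eff / ms_err
            p = float(f_dist.sf(F, df1, dferr))
        out[name] = {"F": float(F), "p": float(p), "df1": df1, "df2": dferr}

    ss_a = 2 * n * float(((mean_a - grand) ** 2).sum())
    ss_as = 2 * float(((mean_sa - mean_s[:, None] - mean_a[None, :] + grand) ** 2).sum())
    _effect("local", ss_a, ss_as, 1, n - 1)

    ss_b = 2 * n * float(((mean_b - grand) ** 2).sum())
    ss_bs = 2 * float(((mean_sb - mean_s[:, None] - mean_b[None, :] + grand) ** 2).sum())
    _effect("global", ss_b, ss_bs, 1, n - 1)

    inter = mean_ab - mean_a[:, None] - mean_b[None, :] + grand
    ss_ab = n * float((inter**2).sum())
    ss_total = float(((Y - grand) ** 2).sum())
    ss_s = 4 * float(((mean_s - grand) ** 2).sum())
    ss_abs = max(ss_total - ss_s - ss_a - ss_b - ss_ab - ss_as - ss_bs, 0.0)
    _effect("interaction", ss_ab, ss_abs, 1, n - 1)
    return out


# ---------------------------------------------------------------------------
# Factorial experiment and window sweep
# ---------------------------------------------------------------------------


def _prepare(cohort: Cohort, plan: SplitPlan) -> tuple[Cohort, Cohort]:
    if any(r.label is None for r in cohort):
        label_cohort(cohort)
    cohort, _ = apply_exclusions(cohort)
    return stratified_split(cohort, plan)


def factorial_experiment(
    cohort: Cohort,
    grid: WindowGrid | None = None,
    classifier=None,
    seed: int = 0,
    folds: int = 20,
    methods: tuple[str, ...] = METHODS,
    dev_fraction: float = 0.30,
    featurizer_kwargs: dict | None = None,
    symbolic_kwargs: dict | None = None,
    _presplit: tuple[Cohort, Cohort] | None = None,
) -> EvalResult:
    """Run the paired factorial comparison on one cohort.

    Labels (if absent) and exclusions are applied, the cohort is split
    30/70, and each requested method is evaluated with k-fold CV on the
    modeling portion using identical fold assignments.  Structural and
    last-value features are computed once per cohort; the symbolic pipeline
    re-fits its discretization and mining inside each training fold (its
    normalization statistics must not leak from test folds).
    """
    grid = grid or WindowGrid()
    plan = SplitPlan(dev_fraction=dev_fraction, folds=folds, seed=seed)
    if _presplit is not None:
        _dev, modeling = _presplit
    else:
        _dev, modeling = _prepare(cohort, plan)
    y = modeling.labels()
    splits = make_folds(y, folds, seed)
    classifier = classifier if classifier is not None else default_classifier(seed)

    def _trend_matrix(mode: str) -> pd.DataFrame:
        feat = TrendFeaturizer(
            mode=mode,
            window_hours=grid.width,
            horizon=grid.horizon,
            **(featurizer_kwargs or {}),
        )
        return feat.fit(modeling.records).transform(modeling.records)

    # local and global structure fits are shared by the combined
    # representation, so compute each block at most once
    cache: dict[str, pd.DataFrame] = {}

    def _matrix(method: str) -> pd.DataFrame:
        if method in cache:
            return cache[method]
        if method == "combined":
            if "local" in cache or "global" in cache or {"local", "global"} & set(methods):
                loc = _matrix("local")
                glo = _matrix("global")
                X = pd.concat([loc, glo], axis=1)
                feat = TrendFeaturizer(
                    mode="combined", window_hours=grid.width, horizon=grid.horizon,
                    **(featurizer_kwargs or {}),
                ).fit(modeling.records[:1])
                X = X[feat.feature_names_]
            else:
                X = _trend_matrix("combined")
        else:
            X = _trend_matrix(method)
        cache[method] = X
        return X

    tables = []
    for method in methods:
        if method == "symbolic":
            est = Pipeline(
                [
                    (
                        "tirps",
                        TIRPFeaturizer(
                            window_hours=grid.width,
                            horizon=grid.horizon,
                            **(symbolic_kwargs or {}),
                        ),
                    ),
                    ("clf", clone(classifier)),
                ]
            )
            res = crossval(modeling.records, y, est, splits=splits)
        elif method in ("last_value", "local", "global", "combined"):
            res = crossval(_matrix(method), y, clone(classifier), splits=splits)
        else:
            raise EvaluationError(f"unknown method {method!r}")
        res.insert(0, "method", method)
        tables.append(res)

    table = pd.concat(tables, ignore_index=True)
    result = EvalResult(table=table)
    wide = result.wide("accuracy")
    if len(wide.columns) >= 2:
        result.anova = rm_anova(wide)
        for a in wide.columns:
            for b in wide.columns:
                if a < b:
                    result.contrasts[f"{a}_vs_{b}"] = rm_anova(wide[[a, b]])
    if all(mth in wide.columns for mth in FACTORIAL_CELLS):
        result.factorial = rm_anova_factorial(wide)
    return result


def window_sweep(
    cohort: Cohort,
    widths: tuple[float, ...] = SUPPORTED_WIDTHS,
    classifier=None,
    seed: int = 0,
    folds: int = 20,
    mode: str = "combined",
    dev_fraction: float = 0.30,
    **kwargs,
) -> pd.DataFrame:
    """Repeat one pipeline per window width on identical folds.

    Returns a per-width metric table (mean accuracy/F1/AUC plus the window
    count m); the argmax-accuracy width is flagged in the ``best`` column.
    """
    for w in widths:
        if w not in SUPPORTED_WIDTHS:
            raise WindowingError(f"width {w} not in supported set {SUPPORTED_WIDTHS}")
    plan = SplitPlan(dev_fraction=dev_fraction, folds=folds, seed=seed)
    _dev, modeling = _prepare(cohort, plan)
    rows = []
    for w in widths:
        grid = WindowGrid(cohort.horizon, w)
        res = factorial_experiment(
            modeling,
            grid=grid,
            classifier=classifier,
            seed=seed,
            folds=folds,
            methods=(mode,),
            _presplit=(Cohort([], cohort.horizon), modeling),
            **kwargs,
        )
        means = res.table[["accuracy", "f1", "auc"]].mean()
        rows.append({"width_hours": w, "m_windows": grid.m, **means.to_dict()})
    out = pd.DataFrame(rows)
    out["best"] = out["accuracy"] == out["accuracy"].max()
    return out


__all__ = [
    "METHODS",
    "FACTORIAL_CELLS",
    "SplitPlan",
    "EvalResult",
    "EvaluationError",
    "split_sizes",
    "stratified_split",
    "default_classifier",
    "make_folds",
    "crossval",
    "rm_anova",
    "rm_anova_factorial",
    "factorial_experiment",
    "window_sweep",
]
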