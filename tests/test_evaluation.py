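"""Splitting, paired cross-validation, repeated-measures ANOVA, sweep."""

import numpy as np
import pandas as pd
import pytest

from trendsieve.cohort import ChannelSeries, Cohort, PatientRecord
from trendsieve.evaluation import (
    EvaluationError,
    SplitPlan,
    crossval,
    default_classifier,
    factorial_experiment,
    make_folds,
    rm_anova,
    rm_anova_factorial,
    split_sizes,
    stratified_split,
    window_sweep,
)
from trendsieve.windowing import WindowingError


def _toy_cohort(n=40, p_pos=0.5, seed=0):
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        label = int(i < round(p_pos * n))
        rec = PatientRecord(
            patient_id=f"t{i}",
            channels={
                "heart_rate": ChannelSeries(
                    "heart_rate", np.array([1.0]), np.array([80.0 + rng.normal()])
                )
            },
            creatinine=ChannelSeries("creatinine", np.array([0.0]), np.array([1.0])),
            label=label,
        )
        records.append(rec)
    return Cohort(records)


class TestSplitSizes:
    def test_reference_cohort_arithmetic(self):
        """30% of a 22,542-patient cohort with 12,848 positives."""
        sizes = split_sizes(22_542, 12_848, 0.30)
        assert sizes["development"] == 6_763
        assert sizes["modeling"] == 15_779
        assert sizes["development_positive"] == 3_855

    def test_small_cohort_rounding(self):
        # N=10, 5 positives, 30%: dev of 3 with round(0.5*3)=2 positives
        sizes = split_sizes(10, 5, 0.3)
        assert sizes["development"] == 3
        assert sizes["development_positive"] == 2


class TestStratifiedSplit:
    def test_partition_is_disjoint_and_exhaustive(self):
        cohort = _toy_cohort(40)
        dev, model = stratified_split(cohort, SplitPlan(seed=1))
        dev_ids = {r.patient_id for r in dev}
        model_ids = {r.patient_id for r in model}
        assert dev_ids.isdisjoint(model_ids)
        assert dev_ids | model_ids == {r.patient_id for r in cohort}

    def test_stratification_preserves_prevalence(self):
        cohort = _toy_cohort(100, p_pos=0.57)
        dev, model = stratified_split(cohort, SplitPlan(seed=2))
        assert int(dev.labels().sum()) == round(0.57 * 30)

    def test_single_class_rejected(self):
        cohort = _toy_cohort(10, p_pos=1.0)
        with pytest.raises(EvaluationError, match="both classes"):
            stratified_split(cohort, SplitPlan(seed=0))

    def test_seed_determinism(self):
        cohort = _toy_cohort(30)
        a1, _ = stratified_split(cohort, SplitPlan(seed=9))
        a2, _ = stratified_split(cohort, SplitPlan(seed=9))
        assert [r.patient_id for r in a1] == [r.patient_id for r in a2]


class TestCrossval:
    def test_separable_data_is_perfect(self):
        y = np.repeat([0, 1], 30)
        X = pd.DataFrame({"f": y * 10.0})
        res = crossval(X, y, default_classifier(0, 50), folds=5, seed=0)
        assert (res.accuracy == 1.0).all()
        assert (res.auc == 1.0).all()

    def test_shuffled_labels_score_near_prevalence(self):
        rng = np.random.default_rng(4)
        y = rng.permutation(np.repeat([0, 1], 50))
        X = pd.DataFrame(rng.normal(size=(100, 5)))
        res = crossval(X, y, default_classifier(0, 50), folds=5, seed=0)
        # binomial CI around chance for n=100
        assert abs(res.accuracy.mean() - 0.5) < 0.17

    def test_fold_assignment_shared_across_methods(self):
        y = np.repeat([0, 1], 20)
        a = make_folds(y, 4, seed=5)
        b = make_folds(y, 4, seed=5)
        for (tr1, te1), (tr2, te2) in zip(a, b):
            assert np.array_equal(te1, te2)

    def test_infeasible_folds_rejected(self):
        y = np.array([0] * 20 + [1] * 3)
        with pytest.raises(EvaluationError, match="need >="):
            make_folds(y, 5, seed=0)


class TestRmAnova:
    def test_matches_hand_sum_of_squares(self):
        # 3 folds x 2 methods, hand-computed one-way repeated measures
        wide = pd.DataFrame({"m1": [0.7, 0.8, 0.6], "m2": [0.9, 0.85, 0.8]})
        out = rm_anova(wide)
        Y = wide.to_numpy()
        grand = Y.mean()
        ss_m = 3 * ((Y.mean(0) - grand) ** 2).sum()
        ss_s = 2 * ((Y.mean(1) - grand) ** 2).sum()
        ss_t = ((Y - grand) ** 2).sum()
        ss_r = ss_t - ss_m - ss_s
        f_hand = (ss_m / 1) / (ss_r / 2)
        assert out["F"] == pytest.approx(f_hand, rel=1e-12)
        assert out["df1"] == 1 and out["df2"] == 2

    def test_identical_methods_give_null_effect(self):
        wide = pd.DataFrame({"a": [0.7, 0.8, 0.75], "b": [0.7, 0.8, 0.75]})
        out = rm_anova(wide)
        assert out["F"] == 0.0 and out["p"] == 1.0

    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        wide = pd.DataFrame(rng.uniform(0.5, 0.9, size=(6, 3)), columns=list("abc"))
        base = rm_anova(wide)
        shifted = rm_anova(wide + 0.1)
        assert base["F"] == pytest.approx(shifted["F"], rel=1e-9)

    def test_incomplete_table_rejected(self):
        wide = pd.DataFrame({"a": [0.7, np.nan], "b": [0.6, 0.5]})
        with pytest.raises(EvaluationError, match="complete"):
            rm_anova(wide)

    def test_matches_statsmodels_on_random_tables(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(11)
        for _ in range(5):
            n, k = int(rng.integers(4, 9)), int(rng.integers(2, 5))
            wide = pd.DataFrame(
                rng.uniform(0, 1, size=(n, k)), columns=[f"m{j}" for j in range(k)]
            )
            long = wide.reset_index().melt(id_vars="index", var_name="method")
            ref = AnovaRM(long, "value", "index", within=["method"]).fit()
            out = rm_anova(wide)
            assert out["F"] == pytest.approx(float(ref.anova_table["F Value"].iloc[0]), rel=1e-8)
            assert out["p"] == pytest.approx(float(ref.anova_table["Pr > F"].iloc[0]), abs=1e-10)


class TestFactorialAnova:
    def test_matches_statsmodels_two_way(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(21)
        for _ in range(5):
            n = int(rng.integers(5, 10))
            wide = pd.DataFrame(
                rng.uniform(0, 1, size=(n, 4)),
                columns=["symbolic", "local", "global", "combined"],
            )
            out = rm_anova_factorial(wide)
            rows = []
            coding = {
                "symbolic": (0, 0),
                "local": (1, 0),
                "global": (0, 1),
                "combined": (1, 1),
            }
            for mth, (a, b) in coding.items():
                for s in range(n):
                    rows.append({"s": s, "A": a, "B": b, "y": wide[mth].iloc[s]})
            ref = AnovaRM(pd.DataFrame(rows), "y", "s", within=["A", "B"]).fit().anova_table
            assert out["local"]["F"] == pytest.approx(float(ref.loc["A", "F Value"]), rel=1e-8)
            assert out["global"]["F"] == pytest.approx(float(ref.loc["B", "F Value"]), rel=1e-8)
            assert out["interaction"]["F"] == pytest.approx(
                float(ref.loc["A:B", "F Value"]), rel=1e-8
            )

    def test_missing_cell_rejected(self):
        wide = pd.DataFrame({"local": [0.1, 0.2], "global": [0.2, 0.3]})
        with pytest.raises(EvaluationError, match="missing cells"):
            rm_anova_factorial(wide)


class TestFactorialExperiment:
    def test_table_shape_and_metric_ranges(self, small_cohort):
        res = factorial_experiment(
            small_cohort,
            seed=0,
            folds=3,
            classifier=default_classifier(0, 50),
            methods=("last_value", "symbolic", "local", "global", "combined"),
        )
        assert len(res.table) == 5 * 3
        for col in ("accuracy", "f1"):
            assert res.table[col].between(0, 1).all()
        assert set(res.table.method) == {
            "last_value",
            "symbolic",
            "local",
            "global",
            "combined",
        }
        assert res.factorial  # 2x2 cells all present
        assert "combined_vs_last_value" in res.contrasts

    def test_unknown_method_rejected(self, small_cohort):
        with pytest.raises(EvaluationError, match="unknown method"):
            factorial_experiment(small_cohort, seed=0, folds=3, methods=("astrology",))


class TestWindowSweep:
    def test_unsupported_width_rejected(self, small_cohort):
        with pytest.raises(WindowingError, match="supported"):
            window_sweep(small_cohort, widths=(48,), folds=3)

    def test_sweep_reports_window_counts_and_best(self, small_cohort):
        out = window_sweep(
            small_cohort,
            widths=(4.0, 8.0),
            folds=3,
            mode="local",
            classifier=default_classifier(0, 50),
            seed=0,
        )
        assert out.m_windows.tolist() == [12, 6]
        assert out.best.sum() >= 1
        again = window_sweep(
            small_cohort,
            widths=(4.0, 8.0),
            folds=3,
            mode="local",
            classifier=default_classifier(0, 50),
            seed=0,
        )
        assert np.allclose(out.accuracy, again.accuracy)
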