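import itertools

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import f1_score

from delirisk import (
    Cohort,
    GeneratorConfig,
    Lem2Classifier,
    auc,
    binary_metrics,
    confusion_from_labels,
    generate_cohort,
    macro_f1,
    paired_wilcoxon,
    stratified_repeated_cv,
    weighted_f1,
)
from delirisk.evaluation import metrics_frame

from conftest import make_record, make_schema

HAND_CONFUSION = {
    ("delirium", "delirium"): 1,
    ("delirium", "non-delirium"): 1,
    ("non-delirium", "delirium"): 0,
    ("non-delirium", "non-delirium"): 97,
}


class TestF1Summaries:
    def test_hand_worked_binary_confusion(self):
        """Per-class F1 66.67 / 99.49; macro is their mean, weighted uses
        true-class counts 2 and 97."""
        assert macro_f1(HAND_CONFUSION) == pytest.approx(83.08, abs=0.005)
        assert weighted_f1(HAND_CONFUSION) == pytest.approx(98.82, abs=0.005)

    def test_agrees_with_sklearn(self):
        """Independent cross-check on label vectors with all degenerate cases."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            y_true = rng.choice(["a", "b", "c"], size=60)
            y_pred = rng.choice(["a", "b", "c"], size=60)
            conf = confusion_from_labels(y_true, y_pred)
            assert macro_f1(conf) == pytest.approx(
                100 * f1_score(y_true, y_pred, average="macro", zero_division=0)
            )
            assert weighted_f1(conf) == pytest.approx(
                100 * f1_score(y_true, y_pred, average="weighted", zero_division=0)
            )

    def test_perfect_diagonal_gives_100(self):
        conf = confusion_from_labels(["a", "b", "a"], ["a", "b", "a"])
        assert macro_f1(conf) == 100.0
        assert weighted_f1(conf) == 100.0

    def test_empty_class_contributes_zero_to_macro(self):
        """A class with no truths and no predictions drags the macro mean."""
        conf = {(t, p): 0 for t in "ab" for p in "ab"}
        conf[("a", "a")] = 10
        assert macro_f1(conf) == 50.0
        assert weighted_f1(conf) == 100.0  # zero weight for the empty class

    def test_macro_equals_weighted_for_balanced_classes(self):
        conf = confusion_from_labels(
            ["a"] * 10 + ["b"] * 10, ["a"] * 8 + ["b"] * 2 + ["b"] * 8 + ["a"] * 2
        )
        assert macro_f1(conf) == pytest.approx(weighted_f1(conf))

    def test_all_zero_confusion_rejected(self):
        with pytest.raises(ValueError):
            macro_f1({})


class TestBinaryMetricsAndAuc:
    def test_hand_arithmetic(self):
        conf = {
            ("delirium", "delirium"): 3,
            ("delirium", "non-delirium"): 1,
            ("non-delirium", "delirium"): 2,
            ("non-delirium", "non-delirium"): 4,
        }
        accuracy, sensitivity, specificity = binary_metrics(conf)
        assert accuracy == pytest.approx(70.0)
        assert sensitivity == pytest.approx(75.0)
        assert specificity == pytest.approx(100 * 4 / 6)

    def test_auc_perfect_and_tied(self):
        labels = ["delirium", "delirium", "non-delirium", "non-delirium"]
        assert auc([1, 1, 0, 0], labels) == 1.0
        assert auc([0.5, 0.5, 0.5, 0.5], labels) == 0.5

    def test_auc_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([1, 0], ["delirium", "delirium"])


def exact_p_by_sign_enumeration(diffs):
    """Brute-force two-sided exact p over all sign assignments."""
    diffs = [d for d in diffs if d != 0]
    ranks = stats.rankdata(np.abs(diffs))
    w_obs = sum(r for d, r in zip(diffs, ranks) if d > 0)
    n = len(diffs)
    w_values = [
        sum(r for keep, r in zip(signs, ranks) if keep)
        for signs in itertools.product([False, True], repeat=n)
    ]
    total = len(w_values)
    cdf = sum(1 for w in w_values if w <= w_obs) / total
    sf = sum(1 for w in w_values if w >= w_obs) / total
    return min(1.0, 2 * min(cdf, sf))


class TestPairedWilcoxon:
    def test_identical_scores_degenerate(self):
        result = paired_wilcoxon([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert result.p_value == 1.0
        assert result.effect_size == 0.0

    def test_uniform_dominance_gives_effect_one(self):
        a = list(range(1, 21))
        b = [x - 1 for x in a]
        result = paired_wilcoxon(a, b)
        assert result.effect_size == 1.0
        assert result.p_value < 0.01

    def test_hand_case_matches_sign_enumeration(self):
        """n = 6 differences +1,+2,+3,-1,+4,+5 (tied absolute ranks)."""
        a = [1, 2, 3, 0, 4, 5]
        b = [0, 0, 0, 1, 0, 0]
        result = paired_wilcoxon(a, b)
        expected = exact_p_by_sign_enumeration(np.subtract(a, b))
        assert result.p_value == pytest.approx(expected)
        assert result.p_value == pytest.approx(0.09375)
        assert result.wilcoxon_statistic == 1.5

    def test_matches_scipy_exact_when_untied(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            ours = paired_wilcoxon(a, b)
            ref = stats.wilcoxon(a, b, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(float(ref.pvalue))

    def test_normal_approximation_branch(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0.3, 1, size=40)
        b = rng.normal(0.0, 1, size=40)
        ours = paired_wilcoxon(a, b)
        ref = stats.wilcoxon(a, b, alternative="two-sided", method="approx")
        assert ours.p_value == pytest.approx(float(ref.pvalue))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            paired_wilcoxon([1, 2], [2, 1])


class PerfectLearner:
    """Memorises the full mapping from factor tuple to label (for noiseless
    rule-generated cohorts the mapping is a function of the features)."""

    def __init__(self, truth=None):
        self.truth = truth

    def get_params(self, deep=True):
        return {"truth": self.truth}

    def set_params(self, **params):
        self.truth = params.get("truth", self.truth)
        return self

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.asarray([self.truth[tuple(row)] for row in X.itertuples(index=False)])


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(GeneratorConfig(n=120, label_noise=0.05, seed=21))


class TestStratifiedRepeatedCV:

    def test_default_protocol_yields_20_folds_partitioning_each_repeat(self, cohort):
        folds = stratified_repeated_cv(cohort, Lem2Classifier(schema=cohort.schema),
                                       k=2, repeats=10, seed=3)
        assert len(folds) == 20
        for r in range(1, 11):
            sizes = [f.test_size for f in folds if f.repeat_index == r]
            assert len(sizes) == 2
            assert sum(sizes) == len(cohort)

    def test_stratification_keeps_class_balance_within_one_record(self, cohort):
        folds = stratified_repeated_cv(cohort, Lem2Classifier(schema=cohort.schema),
                                       k=2, repeats=3, seed=3)
        n_cases = sum(1 for rec in cohort if rec.label == "delirium")
        for f in folds:
            fold_cases = sum(
                v for (t, _), v in f.confusion.items() if t == "delirium"
            )
            expected = n_cases * f.test_size / len(cohort)
            assert abs(fold_cases - expected) <= 1

    def test_determinism_under_fixed_seed(self, cohort):
        kw = dict(k=2, repeats=2, seed=7)
        a = stratified_repeated_cv(cohort, Lem2Classifier(schema=cohort.schema), **kw)
        b = stratified_repeated_cv(cohort, Lem2Classifier(schema=cohort.schema), **kw)
        assert a == b

    def test_perfect_learner_scores_100_on_noiseless_data(self):
        cohort = generate_cohort(GeneratorConfig(n=100, label_noise=0.0, seed=5))
        truth = {
            tuple(rec.value(n) for n in cohort.schema.factor_names): rec.label
            for rec in cohort
        }
        folds = stratified_repeated_cv(cohort, PerfectLearner(truth), k=2, repeats=2, seed=1)
        assert all(f.macro_f1 == 100.0 for f in folds)
        assert all(f.weighted_f1 == 100.0 for f in folds)

    def test_scarce_class_rejected_by_name(self):
        schema = make_schema(2)
        records = tuple(
            make_record(schema, ("yes", "no"), "non-delirium", pid=f"p{i}")
            for i in range(6)
        ) + (make_record(schema, ("no", "yes"), "delirium", pid="solo"),)
        cohort = Cohort(schema=schema, records=records)
        with pytest.raises(ValueError, match="delirium"):
            stratified_repeated_cv(cohort, Lem2Classifier(schema=schema), k=2, repeats=1)

    def test_five_fold_single_repeat_protocol(self, cohort):
        folds = stratified_repeated_cv(cohort, Lem2Classifier(schema=cohort.schema),
                                       k=5, repeats=1, seed=2)
        assert len(folds) == 5
        frame = metrics_frame(folds)
        assert set(frame.columns) >= {"macro_f1", "weighted_f1", "accuracy", "auc"}
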