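"""Validation protocol: repeated stratified CV, F1 summaries, Wilcoxon tests.

The reference protocol is 10-times stratified twofold cross-validation with
per-fold macro-averaged and weighted-average F1, and paired Wilcoxon
signed-rank tests (with matched-pairs rank-biserial effect sizes) between
learners across the 20 fold scores.  Any sklearn-style estimator with
fit/predict can be evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .schema import DELIRIUM, Cohort

__all__ = [
    "FoldMetrics",
    "ComparisonResult",
    "confusion_from_labels",
    "macro_f1",
    "weighted_f1",
    "binary_metrics",
    "auc",
    "paired_wilcoxon",
    "stratified_repeated_cv",
]

Confusion = Mapping[tuple[str, str], int]  # (true, predicted) -> count


def confusion_from_labels(
    y_true: Sequence, y_pred: Sequence, labels: Sequence[str] | None = None
) -> dict[tuple[str, str], int]:
    """Dense (true, predicted) count table over ``labels`` (observed union)."""
    y_true = [str(v) for v in y_true]
    y_pred = [str(v) for v in y_pred]
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    table = {(t, p): 0 for t in labels for p in labels}
    for t, p in zip(y_true, y_pred, strict=True):
        table[(t, p)] += 1
    return table


def _labels_of(confusion: Confusion) -> list[str]:
    labels = sorted({t for t, _ in confusion} | {p for _, p in confusion})
    if not labels or sum(confusion.values()) == 0:
        raise ValueError("confusion table is empty")
    return labels


def _per_class_f1(confusion: Confusion) -> dict[str, tuple[float, int]]:
    """Per-class (F1 fraction, true count); degenerate classes get F1 = 0."""
    labels = _labels_of(confusion)
    out = {}
    for cls in labels:
        tp = confusion.get((cls, cls), 0)
        fn = sum(confusion.get((cls, p), 0) for p in labels if p != cls)
        fp = sum(confusion.get((t, cls), 0) for t in labels if t != cls)
        denom = 2 * tp + fp + fn
        f1 = (2 * tp / denom) if denom else 0.0
        out[cls] = (f1, tp + fn)
    return out


def macro_f1(confusion: Confusion) -> float:
    """Unweighted mean of per-class F1, in percent."""
    scores = _per_class_f1(confusion)
    return 100.0 * sum(f1 for f1, _ in scores.values()) / len(scores)


def weighted_f1(confusion: Confusion, drop_empty: bool = False) -> float:
    """Per-class F1 averaged with true-class-count weights, in percent.

    ``drop_empty`` excludes classes with no truths and no predictions from
    the average instead of counting them as 0 (they carry zero weight here
    either way, but the flag mirrors :func:`macro_f1` semantics downstream).
    """
    scores = _per_class_f1(confusion)
    if drop_empty:
        scores = {c: v for c, v in scores.items() if v[1] > 0}
    total = sum(n for _, n in scores.values())
    if total == 0:
        raise ValueError("no true labels in confusion table")
    return 100.0 * sum(f1 * n for f1, n in scores.values()) / total


def binary_metrics(
    confusion: Confusion, positive: str = DELIRIUM
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent for a binary table."""
    labels = _labels_of(confusion)
    if len(labels) > 2:
        raise ValueError(f"binary metrics need a binary confusion, got classes {labels}")
    if positive not in labels and len(labels) == 2:
        raise ValueError(f"positive class {positive!r} not in confusion classes {labels}")
    negatives = [c for c in labels if c != positive]
    tp = confusion.get((positive, positive), 0)
    fn = sum(confusion.get((positive, n), 0) for n in negatives)
    fp = sum(confusion.get((n, positive), 0) for n in negatives)
    tn = sum(confusion.get((n1, n2), 0) for n1 in negatives for n2 in negatives)
    total = tp + fn + fp + tn
    accuracy = 100.0 * (tp + tn) / total
    sensitivity = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    specificity = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return accuracy, sensitivity, specificity


def auc(scores: Sequence[float], labels: Sequence, positive: str = DELIRIUM) -> float:
    """Area under the ROC curve (fraction) by the rank statistic, tie-corrected."""
    y = np.asarray([1 if str(v) == positive else 0 for v in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both classes present in the labels")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class FoldMetrics:
    """Confusion-derived metrics for one CV test fold."""

    repeat_index: int  # 1..repeats
    fold_index: int  # 1..k
    confusion: dict = field(default_factory=dict)
    macro_f1: float = 0.0
    weighted_f1: float = 0.0
    accuracy: float = 0.0
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    auc: float | None = None

    @property
    def test_size(self) -> int:
        return sum(self.confusion.values())


@dataclass(frozen=True)
class ComparisonResult:
    """Paired Wilcoxon signed-rank comparison of two learners' fold scores."""

    model_a: str
    model_b: str
    metric: str
    wilcoxon_statistic: float
    p_value: float
    effect_size: float  # matched-pairs rank-biserial correlation in [-1, 1]
    n_pairs: int
    n_nonzero: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if not -1.0 <= self.effect_size <= 1.0 + 1e-12:
            raise ValueError("rank-biserial effect size outside [-1, 1]")


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic, ties allowed.

    Enumerates the null distribution of W+ over all sign assignments by
    dynamic programming on doubled ranks (integers even with midranks).
    """
    doubled = np.round(2 * ranks).astype(int)
    total = int(doubled.sum())
    # counts[s] = number of assignments with doubled W+ == s
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    cdf = counts[: w2 + 1].sum()
    sf = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def paired_wilcoxon(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    model_a: str = "A",
    model_b: str = "B",
    metric: str = "macro_f1",
    exact_limit: int = 25,
) -> ComparisonResult:
    """Two-sided paired Wilcoxon signed-rank test with rank-biserial effect.

    Zero differences are dropped.  The exact null distribution is used for up
    to ``exact_limit`` non-zero pairs (including tied ranks); beyond that the
    tie-corrected normal approximation applies.  With all differences zero
    the result degenerates to p = 1, effect 0.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired scores must be equal-length 1-D sequences")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs for a meaningful signed-rank test")
    d = a - b
    nonzero = d[d != 0]
    n = len(nonzero)
    if n == 0:
        return ComparisonResult(model_a, model_b, metric, 0.0, 1.0, 0.0, len(d), 0)
    ranks = stats.rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    w_minus = float(ranks[nonzero < 0].sum())
    statistic = min(w_plus, w_minus)
    if n <= exact_limit:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        p = float(
            stats.wilcoxon(
                nonzero, zero_method="wilcox", alternative="two-sided", method="approx"
            ).pvalue
        )
    effect = (w_plus - w_minus) / (w_plus + w_minus)
    return ComparisonResult(model_a, model_b, metric, statistic, p, float(effect), len(d), n)


def _fold_scores(learner, X_test: pd.DataFrame, y_test: np.ndarray, positive: str):
    """Ranking scores for AUC: probability if available, else 0/1 predictions."""
    if hasattr(learner, "predict_proba"):
        proba = learner.predict_proba(X_test)
        classes = [str(c) for c in learner.classes_]
        if positive in classes:
            return proba[:, classes.index(positive)]
    pred = learner.predict(X_test)
    return np.asarray([1.0 if str(v) == positive else 0.0 for v in pred])


def stratified_repeated_cv(
    cohort: Cohort,
    learner,
    k: int = 2,
    repeats: int = 10,
    seed: int = 0,
    positive: str = DELIRIUM,
) -> list[FoldMetrics]:
    """Repeated stratified k-fold CV of an sklearn-style learner on a cohort.

    Each repeat draws a fresh stratified partition from a per-repeat seed
    derived from ``seed``; every record lands in a test fold exactly once per
    repeat, giving k x repeats fold records (20 under the default 10x2
    protocol).
    """
    if not cohort.labelled:
        raise ValueError("cross-validation requires a labelled cohort")
    df = cohort.to_frame()[list(cohort.schema.factor_names)]
    y = np.asarray([str(v) for v in cohort.labels])
    classes, counts = np.unique(y, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < k:
            raise ValueError(
                f"class {cls!r} has only {cnt} record(s); {k} needed for {k}-fold CV"
            )
    labels = sorted(classes)
    rng = np.random.default_rng(seed)
    repeat_seeds = rng.integers(0, 2**31 - 1, size=repeats)
    out: list[FoldMetrics] = []
    for r in range(repeats):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(repeat_seeds[r]))
        for f, (train_idx, test_idx) in enumerate(splitter.split(df, y)):
            model = clone(learner)
            model.fit(df.iloc[train_idx], y[train_idx])
            pred = model.predict(df.iloc[test_idx])
            conf = confusion_from_labels(y[test_idx], pred, labels=labels)
            acc = sens = spec = float("nan")
            fold_auc = None
            if len(labels) == 2:
                acc, sens, spec = binary_metrics(conf, positive=positive)
                if len(np.unique(y[test_idx])) == 2:
                    scores = _fold_scores(model, df.iloc[test_idx], y[test_idx], positive)
                    fold_auc = auc(scores, y[test_idx], positive=positive)
            else:
                total = sum(conf.values())
                acc = 100.0 * sum(conf.get((c, c), 0) for c in labels) / total
            out.append(
                FoldMetrics(
                    repeat_index=r + 1,
                    fold_index=f + 1,
                    confusion=conf,
                    macro_f1=macro_f1(conf),
                    weighted_f1=weighted_f1(conf),
                    accuracy=acc,
                    sensitivity=sens,
                    specificity=spec,
                    auc=fold_auc,
                )
            )
    return out


def metrics_frame(folds: Sequence[FoldMetrics]) -> pd.DataFrame:
    """Tabular view of fold metrics for reporting."""
    return pd.DataFrame(
        {
            "repeat": [f.repeat_index for f in folds],
            "fold": [f.fold_index for f in folds],
            "test_size": [f.test_size for f in folds],
            "macro_f1": [f.macro_f1 for f in folds],
            "weighted_f1": [f.weighted_f1 for f in folds],
            "accuracy": [f.accuracy for f in folds],
            "sensitivity": [f.sensitivity for f in folds],
            "specificity": [f.specificity for f in folds],
            "auc": [f.auc for f in folds],
        }
    )
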