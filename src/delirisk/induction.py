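"""LEM2 rough-set rule induction and an sklearn-compatible classifier.

LEM2 (Learning from Examples Module 2) builds, for each decision class, a
local covering of that class's rough-set approximation: a set of minimal
attribute-value complexes each of which is *consistent* (its block lies
entirely inside the approximation) and which jointly cover the whole
approximation.  With the default lower approximation the induced rules are
certain rules; inconsistent regions of the data are simply left to the other
class's covering.

Greedy pair selection follows the classic procedure: among candidate
attribute-value pairs drawn from the still-uncovered goal, pick the pair
covering the most goal records; break ties by the smallest total block, then
by schema factor order.  The fixed tie-break makes induction deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .engine import EngineConfig, matching_degree, select_best_rule
from .rules import Condition, Rule, RuleBase, compute_support_confidence
from .schema import (
    DELIRIUM,
    MISSING,
    NON_DELIRIUM,
    Cohort,
    PatientRecord,
    RiskFactor,
    RiskFactorSchema,
)

__all__ = ["InductionConfig", "lem2_induce", "classify", "Lem2Classifier"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InductionConfig:
    """Knobs of the induction run.

    target_class_order: classes to cover, in order (classes absent from the
    cohort are skipped with a warning).
    min_support_pct: rules whose support falls below this are dropped.
    consistency_handling: which rough approximation each class is covered
    against; the lower approximation yields certain rules.
    """

    target_class_order: tuple[str, ...] = (DELIRIUM, NON_DELIRIUM)
    min_support_pct: float = 0.0
    consistency_handling: str = "lower_approximation"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_support_pct <= 100.0:
            raise ValueError("min_support_pct must lie in [0, 100]")
        if self.consistency_handling not in ("lower_approximation", "upper_approximation"):
            raise ValueError(f"unknown consistency handling {self.consistency_handling!r}")


def _value_key(rec: PatientRecord, names: Sequence[str]) -> tuple:
    return tuple(
        None if rec.value(n) is MISSING else rec.value(n) for n in names
    )


def _approximation(cohort: Cohort, cls: str, kind: str) -> frozenset[int]:
    """Indices of the lower/upper rough approximation of class ``cls``.

    Indiscernibility is taken over the full factor vector (MISSING is its own
    value for grouping purposes).
    """
    names = cohort.schema.factor_names
    groups: dict[tuple, list[int]] = {}
    for i, rec in enumerate(cohort):
        groups.setdefault(_value_key(rec, names), []).append(i)
    labels = cohort.labels
    out: set[int] = set()
    for members in groups.values():
        in_cls = [i for i in members if labels[i] == cls]
        if kind == "lower_approximation":
            if len(in_cls) == len(members):
                out.update(members)
        else:
            if in_cls:
                out.update(members)
    return frozenset(out)


def _pair_blocks(cohort: Cohort) -> tuple[list[tuple[str, str]], dict[tuple[str, str], frozenset[int]]]:
    """All attribute-value pairs in schema order with their record blocks.

    The block of (a, v) is the set of record indices with a recorded value v
    for factor a; MISSING belongs to no block.  Factors that are MISSING
    everywhere contribute no pairs (warned).
    """
    order: list[tuple[str, str]] = []
    blocks: dict[tuple[str, str], set[int]] = {}
    for factor in cohort.schema.factors:
        seen_any = False
        for value in factor.allowed_values:
            pair = (factor.name, value)
            block = {
                i for i, rec in enumerate(cohort) if rec.value(factor.name) == value
            }
            if block:
                seen_any = True
                order.append(pair)
                blocks[pair] = block
        if not seen_any:
            warnings.warn(
                f"factor {factor.name!r} is MISSING in every record; ignored",
                stacklevel=3,
            )
    return order, {p: frozenset(b) for p, b in blocks.items()}


def _block_of(T: Sequence[tuple[str, str]], blocks, universe: frozenset[int]) -> frozenset[int]:
    out = universe
    for t in T:
        out = out & blocks[t]
    return out


def _local_covering(
    B: frozenset[int],
    pair_order: list[tuple[str, str]],
    blocks: dict[tuple[str, str], frozenset[int]],
    universe: frozenset[int],
) -> list[tuple[tuple[tuple[str, str], ...], frozenset[int]]]:
    """LEM2 local covering of goal set ``B``; returns (complex, block) pairs."""
    rank = {p: i for i, p in enumerate(pair_order)}
    coverings: list[tuple[tuple[tuple[str, str], ...], frozenset[int]]] = []
    G = set(B)
    while G:
        T: list[tuple[str, str]] = []
        block_T = universe
        G_cur = frozenset(G)
        while not T or not block_T <= B:
            used_factors = {a for a, _ in T}
            candidates = [
                p
                for p in pair_order
                if p[0] not in used_factors and blocks[p] & G_cur
            ]
            if not candidates:
                # records indistinguishable from out-of-goal ones (e.g. all
                # MISSING); they cannot be covered consistently
                uncoverable = block_T & G if T else frozenset(G)
                logger.warning("dropping %d uncoverable goal record(s)", len(uncoverable))
                G -= uncoverable
                T = []
                break
            best = min(
                candidates,
                key=lambda p: (-len(blocks[p] & G_cur), len(blocks[p]), rank[p]),
            )
            T.append(best)
            block_T = block_T & blocks[best]
            G_cur = block_T & G_cur
        if not T:
            continue
        # drop redundant conditions (linear scan in insertion order)
        for t in list(T):
            if len(T) == 1:
                break
            reduced = [u for u in T if u != t]
            if _block_of(reduced, blocks, universe) <= B:
                T = reduced
        block_T = _block_of(T, blocks, universe)
        coverings.append((tuple(T), block_T))
        G -= block_T
    # drop redundant rules: keep T only if removing it breaks completeness
    kept = list(coverings)
    for item in list(kept):
        if len(kept) == 1:
            break
        others = [c for c in kept if c is not item]
        covered = set().union(*(blk for _, blk in others)) if others else set()
        if B <= covered:
            kept = others
    return kept


def lem2_induce(cohort: Cohort, config: InductionConfig | None = None) -> RuleBase:
    """Induce a rule base from a labelled cohort by LEM2 local covering.

    One covering is built per class in ``config.target_class_order``; each
    induced rule carries its training-cohort support and confidence.
    """
    config = config or InductionConfig()
    if not cohort.labelled:
        raise ValueError("LEM2 induction requires a fully labelled cohort")
    present = set(cohort.labels)
    universe = frozenset(range(len(cohort)))
    pair_order, blocks = _pair_blocks(cohort)
    rules: list[Rule] = []
    next_id = 1
    for cls in config.target_class_order:
        if cls not in present:
            warnings.warn(f"class {cls!r} absent from cohort; no rules induced for it",
                          stacklevel=2)
            continue
        B = _approximation(cohort, cls, config.consistency_handling)
        for T, _blk in _local_covering(B, pair_order, blocks, universe):
            conditions = tuple(Condition(a, v) for a, v in T)
            rule = Rule(next_id, conditions, cls)
            support, confidence = compute_support_confidence(rule, cohort)
            if support < config.min_support_pct:
                logger.info("dropping rule %d: support %.3f%% below threshold", next_id, support)
                continue
            rules.append(Rule(next_id, conditions, cls, support, confidence))
            next_id += 1
    provenance = {
        "algorithm": "LEM2",
        "consistency_handling": config.consistency_handling,
        "min_support_pct": config.min_support_pct,
        "support_confidence_scope": "training_cohort",
        "n_records": len(cohort),
    }
    return RuleBase(schema=cohort.schema, rules=tuple(rules), provenance=provenance)


def classify(
    rulebase: RuleBase, record: PatientRecord, mode: str = "strict"
) -> str:
    """Predict a class for ``record`` from a rule base.

    strict: among fully matching rules, the one with the largest
    support x confidence (lowest id on ties) decides; with no full match the
    partial mode takes over.  partial: the best-matching rule decides
    (matching-degree argmax with the same tie-break).
    """
    if len(rulebase) == 0:
        raise ValueError("cannot classify with an empty rule base")
    if mode not in ("strict", "partial"):
        raise ValueError(f"unknown classification mode {mode!r}")
    if mode == "strict":
        full = [r for r in rulebase if matching_degree(r, record) == 100.0]
        if full:
            best = min(full, key=lambda r: (-(r.support * r.confidence), r.rule_id))
            return best.decision
    best = select_best_rule(rulebase, record, EngineConfig())
    return best.decision


class Lem2Classifier(ClassifierMixin, BaseEstimator):
    """Rule-based classifier induced by LEM2, with sklearn fit/predict.

    Accepts a pandas DataFrame (or 2-D array) of categorical/binary factor
    values; ``None``/NaN cells are treated as missing.  After fitting, the
    induced knowledge base is available as ``rulebase_``.

    Parameters
    ----------
    schema : RiskFactorSchema, optional
        Governing schema; inferred from the training data when omitted.
    min_support_pct : float
        Induced rules below this support (percent) are discarded.
    consistency_handling : {"lower_approximation", "upper_approximation"}
        Rough approximation each class is covered against.
    mode : {"strict", "partial"}
        Prediction mode, see :func:`classify`.
    """

    def __init__(
        self,
        schema: RiskFactorSchema | None = None,
        min_support_pct: float = 0.0,
        consistency_handling: str = "lower_approximation",
        mode: str = "strict",
        seed: int = 0,
    ):
        self.schema = schema
        self.min_support_pct = min_support_pct
        self.consistency_handling = consistency_handling
        self.mode = mode
        self.seed = seed

    # -- data adaptation ----------------------------------------------------
    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=object)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        return pd.DataFrame(X, columns=[f"factor_{j + 1}" for j in range(X.shape[1])])

    def _infer_schema(self, df: pd.DataFrame, classes: Sequence[str]) -> RiskFactorSchema:
        factors = []
        for col in df.columns:
            values = sorted({str(v) for v in df[col].dropna().unique()})
            if len(values) < 2:
                values = sorted(set(values) | {"no", "yes"})[:2] if values else ["no", "yes"]
            kind = "binary" if len(values) == 2 else "categorical"
            factors.append(RiskFactor(str(col), kind, tuple(values)))
        return RiskFactorSchema(
            factors=tuple(factors), target_values=tuple(str(c) for c in classes)
        )

    def _to_records(self, df: pd.DataFrame, y=None) -> list[PatientRecord]:
        records = []
        for i, (_, row) in enumerate(df.iterrows()):
            values = {}
            for col in df.columns:
                v = row[col]
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    values[str(col)] = MISSING
                else:
                    values[str(col)] = str(v)
            label = None if y is None else str(y[i])
            records.append(PatientRecord(patient_id=f"r{i}", values=values, label=label))
        return records

    # -- sklearn API --------------------------------------------------------
    def fit(self, X, y):
        df = self._as_frame(X)
        y = np.asarray(y)
        if len(y) != len(df):
            raise ValueError("X and y have different lengths")
        self.classes_ = np.unique(y)
        schema = self.schema or self._infer_schema(df, [str(c) for c in self.classes_])
        order = tuple(
            c for c in (DELIRIUM, NON_DELIRIUM) if c in {str(v) for v in self.classes_}
        ) or tuple(str(c) for c in self.classes_)
        cohort = Cohort(schema=schema, records=tuple(self._to_records(df, y)))
        config = InductionConfig(
            target_class_order=order,
            min_support_pct=self.min_support_pct,
            consistency_handling=self.consistency_handling,
            seed=self.seed,
        )
        self.schema_ = schema
        self.rulebase_ = lem2_induce(cohort, config)
        self.n_features_in_ = df.shape[1]
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        return self

    def predict(self, X):
        check_is_fitted(self, "rulebase_")
        df = self._as_frame(X)
        records = self._to_records(df)
        out = [classify(self.rulebase_, rec, mode=self.mode) for rec in records]
        # restore original label dtype where possible
        lookup = {str(c): c for c in self.classes_}
        return np.asarray([lookup.get(v, v) for v in out])

    def fit_cohort(self, cohort: Cohort) -> "Lem2Classifier":
        """Fit directly from a labelled :class:`Cohort`."""
        df = cohort.to_frame()[list(cohort.schema.factor_names)]
        self.schema = cohort.schema
        return self.fit(df, np.asarray(cohort.labels))
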