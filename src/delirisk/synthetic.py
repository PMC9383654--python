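"""Synthetic long-term-care cohorts with planted rule structure.

Factor values are drawn independently per factor; the delirium label is
rule-driven: a record fully satisfying any planted delirium rule is labelled
delirium, and a residual Bernoulli component among the remaining records
tops overall incidence up towards the configured base prevalence (8.1% by
default, the reported delirium incidence in long-term care facilities).
Optional label noise flips each final label independently.  Rule-driven
labels make rule recovery well-defined for the induction tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .rules import Condition, Rule, RuleBase
from .schema import (
    DELIRIUM,
    NON_DELIRIUM,
    Cohort,
    PatientRecord,
    RiskFactorSchema,
    default_schema,
)

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "default_planted_rules",
    "RecoveryReport",
    "rule_recovery_report",
]

# Surname-style pseudonyms for generated patient ids (cycled with a counter).
_PSEUDONYMS = (
    "Kim", "Lee", "Park", "Choi", "Jung", "Kang", "Cho", "Yoon", "Jang", "Lim",
    "Han", "Oh", "Seo", "Shin", "Kwon", "Hwang", "Ahn", "Song", "Yang", "Hong",
)


def default_planted_rules(schema: RiskFactorSchema | None = None) -> RuleBase:
    """Three disjoint two-factor delirium rules over the default schema.

    Each pairs two clinically plausible precipitating factors; disjoint
    factor sets keep the planted mechanism identifiable.
    """
    schema = schema or default_schema()
    pairs = (
        ("age_65_or_older", "dehydration"),
        ("infection", "sleep_disorder"),
        ("hypoxia", "surgery_general_anaesthesia"),
    )
    rules = []
    for i, (a, b) in enumerate(pairs, start=1):
        yes_a = schema.factor(a).allowed_values[-1]
        yes_b = schema.factor(b).allowed_values[-1]
        rules.append(
            Rule(i, (Condition(a, yes_a), Condition(b, yes_b)), DELIRIUM)
        )
    return RuleBase(schema=schema, rules=tuple(rules), provenance={"origin": "planted"})


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    n: cohort size (default 173, the reference cohort size).
    base_prevalence: target overall delirium incidence (default 0.081).
    factor_marginals: per-factor probability of the positive value
    (default 0.20 for every factor).
    label_noise: probability each final label is flipped.
    """

    n: int = 173
    schema: RiskFactorSchema | None = None
    planted_rules: RuleBase | None = None
    base_prevalence: float = 0.081
    label_noise: float = 0.0
    factor_marginals: Mapping[str, float] | float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if not 0.0 <= self.base_prevalence <= 1.0:
            raise ValueError("base_prevalence must lie in [0, 1]")
        if not 0.0 <= self.label_noise <= 0.5:
            raise ValueError("label_noise must lie in [0, 0.5]")


def _marginal(config: GeneratorConfig, name: str) -> float:
    m = config.factor_marginals
    p = m.get(name, 0.20) if isinstance(m, Mapping) else float(m)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"marginal for {name!r} outside [0, 1]")
    return p


def generate_cohort(config: GeneratorConfig | None = None) -> Cohort:
    """Draw one labelled cohort; deterministic given ``config.seed``."""
    config = config or GeneratorConfig()
    schema = config.schema or default_schema()
    planted = (
        config.planted_rules
        if config.planted_rules is not None
        else default_planted_rules(schema)
    )
    for rule in planted:
        rule.validate_against(schema)
    rng = np.random.default_rng(config.seed)
    records = []
    for i in range(config.n):
        values = {}
        for factor in schema.factors:
            # positive value = last allowed value; others split the remainder
            p = _marginal(config, factor.name)
            if rng.random() < p:
                values[factor.name] = factor.allowed_values[-1]
            else:
                others = factor.allowed_values[:-1]
                values[factor.name] = others[rng.integers(len(others))]
        pid = f"{_PSEUDONYMS[i % len(_PSEUDONYMS)]}-{i:04d}"
        records.append(PatientRecord(patient_id=pid, values=values))

    covered = [any(rule.covers(rec) for rule in planted) for rec in records]
    n_covered = sum(covered)
    n_uncovered = config.n - n_covered
    target_cases = config.base_prevalence * config.n
    residual_p = 0.0
    if n_uncovered > 0:
        residual_p = min(1.0, max(0.0, (target_cases - n_covered) / n_uncovered))
    labels = []
    for rec, is_covered in zip(records, covered):
        if is_covered:
            label = DELIRIUM
        elif residual_p > 0 and rng.random() < residual_p:
            label = DELIRIUM
        else:
            label = NON_DELIRIUM
        if config.label_noise > 0 and rng.random() < config.label_noise:
            label = NON_DELIRIUM if label == DELIRIUM else DELIRIUM
        labels.append(label)
    records = [
        PatientRecord(rec.patient_id, rec.values, label)
        for rec, label in zip(records, labels)
    ]
    return Cohort(schema=schema, records=tuple(records))


@dataclass(frozen=True)
class RecoveryReport:
    """Per-planted-rule recovery of an induced rule base."""

    exact: dict[int, bool] = field(default_factory=dict)
    coverage_equivalent: dict[int, bool] = field(default_factory=dict)

    @property
    def exact_pct(self) -> float:
        return 100.0 * sum(self.exact.values()) / len(self.exact) if self.exact else 0.0

    @property
    def coverage_pct(self) -> float:
        vals = self.coverage_equivalent
        return 100.0 * sum(vals.values()) / len(vals) if vals else 0.0


def rule_recovery_report(
    planted: RuleBase, induced: RuleBase, cohort: Cohort
) -> RecoveryReport:
    """Compare an induced rule base against the planted ground truth.

    A planted rule is *exactly* recovered when some induced rule shares its
    condition set and decision; it is *coverage-equivalent* when some induced
    rule of the same decision covers exactly the same records of the
    reference cohort.
    """
    if planted.schema.factor_names != induced.schema.factor_names:
        raise ValueError("planted and induced rule bases use different schemas")
    exact: dict[int, bool] = {}
    cov_eq: dict[int, bool] = {}
    induced_cover = {
        r.rule_id: frozenset(i for i, rec in enumerate(cohort) if r.covers(rec))
        for r in induced
    }
    for p in planted:
        p_conditions = frozenset(p.conditions)
        exact[p.rule_id] = any(
            frozenset(r.conditions) == p_conditions and r.decision == p.decision
            for r in induced
        )
        p_cover = frozenset(i for i, rec in enumerate(cohort) if p.covers(rec))
        cov_eq[p.rule_id] = any(
            induced_cover[r.rule_id] == p_cover and r.decision == p.decision
            for r in induced
        )
    return RecoveryReport(exact=exact, coverage_equivalent=cov_eq)
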