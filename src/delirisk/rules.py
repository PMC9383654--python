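"""IF-THEN classification rules with support/confidence, stored as JSON.

The knowledge base of the decision-support engine is a list of
class-association rules.  Support is the joint frequency of the rule's
antecedent and consequent as a percentage of all training records; confidence
is the conditional frequency among records satisfying the antecedent.  Both
are kept on the rule so the inference engine can rank candidates without
re-touching the training data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .schema import MISSING, Cohort, PatientRecord, RiskFactorSchema, SchemaError

__all__ = [
    "Condition",
    "Rule",
    "RuleBase",
    "RuleError",
    "compute_support_confidence",
    "save_rulebase",
    "load_rulebase",
]


class RuleError(ValueError):
    """A rule or rule base violates its structural invariants."""


@dataclass(frozen=True)
class Condition:
    """One antecedent clause: ``factor == value``."""

    factor: str
    value: str

    def satisfied_by(self, record: PatientRecord) -> bool:
        v = record.value(self.factor)
        return v is not MISSING and v == self.value


@dataclass(frozen=True)
class Rule:
    """IF conditions THEN decision, annotated with support and confidence (%)."""

    rule_id: int
    conditions: tuple[Condition, ...]
    decision: str
    support: float = 0.0
    confidence: float = 0.0

    def __post_init__(self) -> None:
        conditions = tuple(self.conditions)
        if self.rule_id < 1:
            raise RuleError(f"rule_id must be >= 1, got {self.rule_id}")
        if not conditions:
            raise RuleError(f"rule {self.rule_id}: conditions must be non-empty")
        factors = [c.factor for c in conditions]
        if len(set(factors)) != len(factors):
            raise RuleError(f"rule {self.rule_id}: duplicate factor in conditions")
        for name, v in (("support", self.support), ("confidence", self.confidence)):
            if not 0.0 <= v <= 100.0:
                raise RuleError(f"rule {self.rule_id}: {name} {v} outside [0, 100]")
        object.__setattr__(self, "conditions", conditions)

    def covers(self, record: PatientRecord) -> bool:
        """True iff every condition is satisfied (MISSING never satisfies)."""
        return all(c.satisfied_by(record) for c in self.conditions)

    def validate_against(self, schema: RiskFactorSchema) -> None:
        for c in self.conditions:
            if c.factor not in schema:
                raise RuleError(f"rule {self.rule_id}: unknown factor {c.factor!r}")
            if c.value not in schema.factor(c.factor).allowed_values:
                raise RuleError(
                    f"rule {self.rule_id}: illegal value {c.value!r} for factor {c.factor!r}"
                )
        if self.decision not in schema.target_values:
            raise RuleError(f"rule {self.rule_id}: unknown decision {self.decision!r}")


@dataclass(frozen=True)
class RuleBase:
    """A schema-validated rule collection plus free-text provenance."""

    schema: RiskFactorSchema
    rules: tuple[Rule, ...]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rules = tuple(self.rules)
        ids = [r.rule_id for r in rules]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RuleError(f"duplicate rule_id(s): {dupes}")
        for r in rules:
            r.validate_against(self.schema)
        object.__setattr__(self, "rules", rules)
        object.__setattr__(self, "provenance", dict(self.provenance))

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def for_decision(self, decision: str) -> tuple[Rule, ...]:
        return tuple(r for r in self.rules if r.decision == decision)


def compute_support_confidence(rule: Rule, cohort: Cohort) -> tuple[float, float]:
    """Support and confidence (%) of ``rule`` over a labelled cohort.

    Records with MISSING on a condition factor do not satisfy the antecedent.
    A rule whose antecedent matches no record gets confidence 0 by convention.
    """
    if not cohort.labelled:
        raise ValueError("support/confidence require a fully labelled cohort")
    rule.validate_against(cohort.schema)
    n = len(cohort)
    covered = sum(1 for rec in cohort if rule.covers(rec))
    hits = sum(1 for rec in cohort if rule.covers(rec) and rec.label == rule.decision)
    support = 100.0 * hits / n
    confidence = 100.0 * hits / covered if covered else 0.0
    return support, confidence


def _rule_to_dict(rule: Rule) -> dict:
    return {
        "id": rule.rule_id,
        "if": [{"factor": c.factor, "value": c.value} for c in rule.conditions],
        "then": rule.decision,
        "support": rule.support,
        "confidence": rule.confidence,
    }


def _rule_from_dict(data: Mapping) -> Rule:
    try:
        conditions = tuple(Condition(c["factor"], c["value"]) for c in data["if"])
        return Rule(
            rule_id=int(data["id"]),
            conditions=conditions,
            decision=data["then"],
            support=float(data.get("support", 0.0)),
            confidence=float(data.get("confidence", 0.0)),
        )
    except (KeyError, TypeError) as exc:
        raise RuleError(f"malformed rule document: {exc}") from exc


def save_rulebase(rulebase: RuleBase, path: str | Path) -> Path:
    """Serialize a rule base to the interoperable JSON knowledge format."""
    doc = {
        "schema": rulebase.schema.to_dict(),
        "rules": [_rule_to_dict(r) for r in rulebase.rules],
        "provenance": dict(rulebase.provenance),
    }
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
    return path


def load_rulebase(path: str | Path, schema: RiskFactorSchema | None = None) -> RuleBase:
    """Load and re-validate a rule base; ``schema`` overrides the embedded one."""
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise RuleError(f"malformed rule-base JSON in {path}: {exc}") from exc
    if schema is None:
        if "schema" not in doc:
            raise SchemaError(f"{path} embeds no schema and none was supplied")
        schema = RiskFactorSchema.from_dict(doc["schema"])
    rules = tuple(_rule_from_dict(r) for r in doc.get("rules", ()))
    return RuleBase(schema=schema, rules=rules, provenance=doc.get("provenance", {}))


def renumber(rules: Iterable[Rule], start: int = 1) -> tuple[Rule, ...]:
    """Reassign consecutive rule ids, preserving order."""
    out = []
    for i, r in enumerate(rules, start=start):
        out.append(Rule(i, r.conditions, r.decision, r.support, r.confidence))
    return tuple(out)
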