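"""Knowledge-based reasoning: matching degree, best rule, risk level, alarm.

Given a (possibly incomplete) patient record and a rule base, the engine
computes each rule's matching degree — the percentage of its conditions the
record satisfies — picks the best rule (highest matching degree, ties broken
by the largest support x confidence product, residual ties by lowest rule
id), and when the winning rule decides delirium, stratifies the patient into
low / medium / high risk by the rule's support against tertile cut-offs
(defaults 1.73% and 3.47%, the 33.3rd and 66.7th percentiles of the shipped
knowledge base's rule supports).  A delirium decision raises an alarm event.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

from .rules import Rule, RuleBase
from .schema import DELIRIUM, PatientRecord

__all__ = [
    "EngineConfig",
    "PredictionResult",
    "matching_degree",
    "select_best_rule",
    "stratify_risk",
    "predict",
]

RISK_LEVELS = ("low", "medium", "high", "none")


@dataclass(frozen=True)
class EngineConfig:
    """Inference thresholds and alarm channels.

    tau_low / tau_high: support tertile cut-offs in percent. The middle band
    is the closed interval [tau_low, tau_high].
    min_matching_degree: below this best matching degree (percent) the engine
    reports no match instead of guessing; 0 keeps the always-answer behaviour
    of the deployed app.
    """

    tau_low: float = 1.73
    tau_high: float = 3.47
    min_matching_degree: float = 0.0
    alarm_channels: tuple[str, ...] = ("screen", "vibration")

    def __post_init__(self) -> None:
        if not 0.0 < self.tau_low < self.tau_high < 100.0:
            raise ValueError(
                f"need 0 < tau_low < tau_high < 100, got {self.tau_low}, {self.tau_high}"
            )
        allowed = {"screen", "vibration", "sound"}
        channels = tuple(self.alarm_channels)
        if not set(channels) <= allowed:
            raise ValueError(f"alarm channels must be a subset of {sorted(allowed)}")
        object.__setattr__(self, "alarm_channels", channels)


@dataclass(frozen=True)
class PredictionResult:
    """Outcome of one inference pass for one patient."""

    best_rule_id: int
    matching_degree: float
    risk_percent: float  # the matched rule's support
    risk_level: str  # low | medium | high | none
    predicted_class: str
    alarm: bool

    def __post_init__(self) -> None:
        if (self.risk_level == "none") != (self.predicted_class != DELIRIUM):
            raise ValueError("risk_level is 'none' exactly for non-delirium predictions")
        if self.alarm != (self.predicted_class == DELIRIUM):
            raise ValueError("alarm fires exactly for delirium predictions")


def matching_degree(rule: Rule, record: PatientRecord) -> float:
    """Percentage of the rule's conditions the record satisfies.

    A MISSING factor value never satisfies a condition.
    """
    satisfied = sum(1 for c in rule.conditions if c.satisfied_by(record))
    return 100.0 * satisfied / len(rule.conditions)


def select_best_rule(
    rulebase: RuleBase, record: PatientRecord, config: EngineConfig | None = None
) -> Rule | None:
    """The rule with the highest matching degree for ``record``.

    Ties on matching degree are broken by the largest support x confidence
    product; residual ties by the lowest rule id.  Returns None when the best
    matching degree falls below ``config.min_matching_degree``.
    """
    config = config or EngineConfig()
    if len(rulebase) == 0:
        raise ValueError("cannot select a rule from an empty rule base")
    best = min(
        rulebase,
        key=lambda r: (
            -matching_degree(r, record),
            -(r.support * r.confidence),
            r.rule_id,
        ),
    )
    if matching_degree(best, record) < config.min_matching_degree:
        return None
    return best


def stratify_risk(rule: Rule, config: EngineConfig | None = None) -> str:
    """Tertile risk level for a delirium rule: cut by its support.

    low: support < tau_low; medium: tau_low <= support <= tau_high (closed
    interval); high: support > tau_high.
    """
    config = config or EngineConfig()
    if rule.decision != DELIRIUM:
        raise ValueError(f"risk stratification applies to delirium rules only, got {rule.decision!r}")
    if rule.support < config.tau_low:
        return "low"
    if rule.support <= config.tau_high:
        return "medium"
    return "high"


def predict(
    record: PatientRecord,
    rulebase: RuleBase,
    config: EngineConfig | None = None,
    audit_log: "str | Path | AuditLog | None" = None,
) -> PredictionResult | None:
    """Full inference for one record: best rule, risk level, alarm flag.

    Returns None when no rule reaches ``min_matching_degree``.  When an
    ``audit_log`` is given, the inputs and result are appended to it.
    """
    config = config or EngineConfig()
    best = select_best_rule(rulebase, record, config)
    if best is None:
        return None
    degree = matching_degree(best, record)
    if best.decision == DELIRIUM:
        level = stratify_risk(best, config)
        alarm = True
    else:
        level = "none"
        alarm = False
    result = PredictionResult(
        best_rule_id=best.rule_id,
        matching_degree=degree,
        risk_percent=best.support,
        risk_level=level,
        predicted_class=best.decision,
        alarm=alarm,
    )
    if audit_log is not None:
        log = audit_log if isinstance(audit_log, AuditLog) else AuditLog(audit_log)
        log.append(record, result, config)
    return result


@dataclass
class AuditLog:
    """JSON-lines audit trail of inference events (alarm = an event record)."""

    path: str | Path
    entries: list = field(default_factory=list)

    def append(
        self, record: PatientRecord, result: PredictionResult, config: EngineConfig
    ) -> dict:
        entry = {
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "patient_id": record.patient_id,
            "result": asdict(result),
            "alarm_channels": list(config.alarm_channels) if result.alarm else [],
        }
        self.entries.append(entry)
        with open(self.path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps(entry) + "\n")
        return entry
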