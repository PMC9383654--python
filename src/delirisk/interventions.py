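"""Multi-component preventive intervention checklists and performance rate.

Three non-pharmacological components are offered: orientation interventions,
environmental interventions, and early avoidance of delirium risk factors.
Nurses mark items complete; the performance rate is the completed percentage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

from .scam import ScamResult

__all__ = [
    "CATEGORIES",
    "DEFAULT_CATALOGUE",
    "InterventionItem",
    "InterventionPlan",
    "build_plan",
    "performance_rate",
    "save_plan",
    "load_plan",
]

CATEGORIES = ("orientation", "environmental", "risk_avoidance")

# Shipped item catalogue, one entry per checklist action of the three
# components of the deployed app.
DEFAULT_CATALOGUE: Mapping[str, tuple[str, ...]] = {
    "orientation": (
        "Provide a clock or calendar for repeated orientation",
        "Use the patient's name when providing care",
        "Place familiar objects close to the patient",
        "Encourage family members to visit regularly",
        "Detect abnormalities early",
        "Encourage regular involvement in activities of daily living",
        "Provide eyeglasses, hearing aids or other sensory assistive devices",
    ),
    "environmental": (
        "Use indirect lighting and reduce ambient noise for sleep",
        "Keep the same nurse in the same ward",
        "Distinguish day and night with window curtains or blinds",
        "Encourage the patient to continue hobbies (music, games, knitting)",
        "Provide or read newspapers daily",
        "Encourage meaningful conversations to stimulate memory and reasoning",
    ),
    "risk_avoidance": (
        "Provide an appropriate amount of water and prevent dehydration",
        "Manage pain pharmacologically and non-pharmacologically",
        "Minimise the use of physical restraints",
        "Provide active and passive range-of-motion exercises",
        "Encourage walking",
        "Evaluate nutritional intake and provide non-oral feeding if necessary",
        "Detect and treat infection early",
        "Use anticholinergic drugs and opioids cautiously; minimise unnecessary drugs",
        "Monitor for hypoxia",
        "Prevent constipation, falls and pressure ulcers",
    ),
}


@dataclass
class InterventionItem:
    category: str
    text: str
    completed: bool = False
    timestamp: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown intervention category {self.category!r}")
        if not self.text:
            raise ValueError("intervention item text must be non-empty")


@dataclass
class InterventionPlan:
    patient_id: str
    items: list[InterventionItem] = field(default_factory=list)

    def __post_init__(self) -> None:
        texts = [it.text for it in self.items]
        if len(set(texts)) != len(texts):
            raise ValueError("duplicate item text within one plan")

    def __len__(self) -> int:
        return len(self.items)

    def categories(self) -> set[str]:
        return {it.category for it in self.items}

    def mark_completed(self, text: str, timestamp: str | None = None) -> None:
        for it in self.items:
            if it.text == text:
                it.completed = True
                it.timestamp = timestamp
                return
        raise KeyError(f"no such item in plan: {text!r}")


def _validated_catalogue(catalogue: Mapping[str, Sequence[str]]) -> Mapping[str, tuple[str, ...]]:
    all_texts: list[str] = []
    out = {}
    for category, texts in catalogue.items():
        if category not in CATEGORIES:
            raise ValueError(f"unknown intervention category {category!r}")
        out[category] = tuple(texts)
        all_texts.extend(texts)
    if len(set(all_texts)) != len(all_texts):
        raise ValueError("duplicate item text in catalogue")
    return out


def build_plan(
    risk_level: str,
    scam: ScamResult | None,
    catalogue: Mapping[str, Sequence[str]] | None = None,
    patient_id: str = "anonymous",
    policy: str = "preventive",
) -> InterventionPlan:
    """Issue a checklist plan according to risk level and S-CAM screen.

    ``policy="strict"`` issues the full three-component plan only for
    high-risk patients screening positive; the default ``"preventive"``
    policy also issues it for high risk alone or any positive screen, since
    the components are preventive.  Ineligible patients get an empty plan.
    """
    if risk_level not in ("low", "medium", "high", "none"):
        raise ValueError(f"unknown risk level {risk_level!r}")
    if policy not in ("strict", "preventive"):
        raise ValueError(f"unknown eligibility policy {policy!r}")
    catalogue = _validated_catalogue(catalogue or DEFAULT_CATALOGUE)
    positive = scam is not None and scam.delirium_positive
    if policy == "strict":
        eligible = risk_level == "high" and positive
    else:
        eligible = risk_level == "high" or positive
    items: list[InterventionItem] = []
    if eligible:
        for category in CATEGORIES:
            for text in catalogue.get(category, ()):
                items.append(InterventionItem(category=category, text=text))
    return InterventionPlan(patient_id=patient_id, items=items)


def performance_rate(plan: InterventionPlan) -> float:
    """Completed percentage of the plan, half-up rounded to one decimal."""
    if len(plan) == 0:
        raise ValueError("performance rate is undefined for an empty plan")
    done = sum(1 for it in plan.items if it.completed)
    raw = Decimal(100 * done) / Decimal(len(plan))
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def save_plan(plan: InterventionPlan, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(asdict(plan), fh, indent=1)
    return path


def load_plan(path: str | Path) -> InterventionPlan:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    items = [InterventionItem(**it) for it in doc.get("items", [])]
    return InterventionPlan(patient_id=doc["patient_id"], items=items)
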