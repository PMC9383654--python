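"""Short Confusion Assessment Method (S-CAM) decision logic.

The instrument has four steps: (1) acute onset and fluctuating course,
(2) inattention, (3) disorganized thinking, (4) altered level of
consciousness, rated on a five-level scale (normal, vigilant, lethargic,
stuporous, comatose).  The embedded app rule screens positive when the
inattention step is YES, at least one item of Box 1 (steps 1-2) is YES, and
at least one item of Box 2 (steps 3-4) is YES; any non-normal consciousness
level counts as a YES for step 4.  Only the decision logic is implemented
here — the licensed instrument text is not reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ScamResponses", "ScamResult", "assess_scam", "CONSCIOUSNESS_LEVELS"]

CONSCIOUSNESS_LEVELS = ("normal", "vigilant", "lethargic", "stuporous", "comatose")
SUBTYPES = ("hyperactive", "hypoactive", "mixed")


@dataclass(frozen=True)
class ScamResponses:
    """Raw four-step responses (step 1 has two items)."""

    step1_acute_onset: bool
    step1_fluctuation: bool
    step2_inattention: bool
    step3_disorganized_thinking: bool
    step4_consciousness: str

    def __post_init__(self) -> None:
        for name in (
            "step1_acute_onset",
            "step1_fluctuation",
            "step2_inattention",
            "step3_disorganized_thinking",
        ):
            if not isinstance(getattr(self, name), bool):
                raise ValueError(f"{name} must be a boolean")
        if self.step4_consciousness not in CONSCIOUSNESS_LEVELS:
            raise ValueError(
                f"consciousness must be one of {CONSCIOUSNESS_LEVELS}, "
                f"got {self.step4_consciousness!r}"
            )


@dataclass(frozen=True)
class ScamResult:
    """Delirium(+/-) determination; subtype is recorded, never computed."""

    delirium_positive: bool
    box1_any_yes: bool
    box2_any_yes: bool
    subtype: str | None = None

    def __post_init__(self) -> None:
        if self.subtype is not None and self.subtype not in SUBTYPES:
            raise ValueError(f"subtype must be one of {SUBTYPES}")
        if self.delirium_positive and not (self.box1_any_yes and self.box2_any_yes):
            raise ValueError("a positive screen requires a YES in both boxes")


def assess_scam(
    responses: ScamResponses,
    subtype: str | None = None,
    standard_cam: bool = False,
) -> ScamResult:
    """Apply the screening rule to a set of responses.

    Default (app rule): positive iff step 2 is YES, Box 1 (steps 1-2) has at
    least one YES, and Box 2 (steps 3-4) has at least one YES.  Since a YES
    on step 2 already satisfies Box 1, this reduces to step2 AND box2.

    ``standard_cam=True`` switches to the conventional CAM feature logic:
    (acute onset OR fluctuation) AND inattention AND (disorganized thinking
    OR altered consciousness).
    """
    step4_yes = responses.step4_consciousness != "normal"
    box1 = (
        responses.step1_acute_onset
        or responses.step1_fluctuation
        or responses.step2_inattention
    )
    box2 = responses.step3_disorganized_thinking or step4_yes
    if standard_cam:
        feature1 = responses.step1_acute_onset or responses.step1_fluctuation
        positive = feature1 and responses.step2_inattention and box2
    else:
        positive = responses.step2_inattention and box1 and box2
    return ScamResult(
        delirium_positive=positive,
        box1_any_yes=box1,
        box2_any_yes=box2,
        subtype=subtype if positive else None,
    )
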