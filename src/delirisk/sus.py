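"""System Usability Scale (SUS) scoring.

Ten Likert items rated 1-5.  Standard (Brooke) scoring: odd items contribute
(value - 1), even items contribute (5 - value); the sum of contributions is
multiplied by 2.5, giving a 0-100 scale with 68 as the conventional
above-average benchmark.  A literal raw-sum x 2.5 mode is also provided for
transparency; note it spans 25-125, not 0-100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = ["SusResponse", "SusScore", "sus_score", "SUS_BENCHMARK"]

SUS_BENCHMARK = 68.0


@dataclass(frozen=True)
class SusResponse:
    """Exactly ten Likert ratings, each an integer in 1..5."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        items = tuple(self.items)
        if len(items) != 10:
            raise ValueError(f"a SUS response has exactly 10 items, got {len(items)}")
        for i, v in enumerate(items, start=1):
            if not isinstance(v, int) or isinstance(v, bool) or not 1 <= v <= 5:
                raise ValueError(f"item {i} must be an integer in 1..5, got {v!r}")
        object.__setattr__(self, "items", items)


@dataclass(frozen=True)
class SusScore:
    score: float
    above_average: bool
    mode: str


def sus_score(response: SusResponse | Sequence[int], mode: str = "standard") -> SusScore:
    """Score one SUS response.

    standard: Brooke scoring on a 0-100 scale (default).
    paper_literal: raw item sum x 2.5 (spans 25-125).
    The above-average flag fires at a score of 68 or higher in either mode.
    """
    if not isinstance(response, SusResponse):
        response = SusResponse(tuple(response))
    if mode == "standard":
        total = sum(
            (v - 1) if i % 2 == 1 else (5 - v)
            for i, v in enumerate(response.items, start=1)
        )
    elif mode == "paper_literal":
        total = sum(response.items)
    else:
        raise ValueError(f"unknown SUS scoring mode {mode!r}")
    score = total * 2.5
    return SusScore(score=score, above_average=score >= SUS_BENCHMARK, mode=mode)


def score_survey(
    responses: Iterable[Sequence[int]], mode: str = "standard"
) -> tuple[list[SusScore], float]:
    """Score a batch of responses; returns per-respondent scores and the mean."""
    scores = [sus_score(r, mode=mode) for r in responses]
    if not scores:
        raise ValueError("no responses to score")
    mean = sum(s.score for s in scores) / len(scores)
    return scores, mean
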