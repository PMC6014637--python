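"""Domain types for a two-round structured elicitation.

The data model mirrors the four-step question format: each participant
supplies, per question and round, a lowest plausible value, a highest
plausible value, a best estimate, and the confidence (in percent) that
the truth lies between the bounds.  Questions carry hard domain bounds
(e.g. a density cannot be negative), a grain size — the smallest change
in the question's units considered consequential — and, once the event
is realised, the observed value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable

import pandas as pd

from .errors import ValidationError


@dataclass
class Question:
    """One elicited quantity.

    Attributes
    ----------
    question_id : str
        Unique identifier.
    topic : str
        Free-text description of what is being estimated.
    domain_min, domain_max : float
        Hard bounds of the measured quantity; ``-inf`` / ``+inf`` when
        unbounded.
    grain_size : float
        Positive threshold, in question units, above which a change of a
        best estimate is deemed meaningful.
    realised_value : float or None
        The observed outcome, absent until the question is validated.
    validated : bool
        Whether the realised value is available and trustworthy.
    """

    question_id: str
    topic: str = ""
    domain_min: float = -math.inf
    domain_max: float = math.inf
    grain_size: float = 1.0
    realised_value: float | None = None
    validated: bool = False

    def check(self) -> list[str]:
        problems = []
        if not self.domain_min < self.domain_max:
            problems.append(
                f"question {self.question_id}: domain_min must be < domain_max"
            )
        if not self.grain_size > 0:
            problems.append(f"question {self.question_id}: grain_size must be > 0")
        if self.realised_value is not None and not (
            self.domain_min <= self.realised_value <= self.domain_max
        ):
            problems.append(
                f"question {self.question_id}: realised_value outside domain bounds"
            )
        if self.validated and self.realised_value is None:
            problems.append(
                f"question {self.question_id}: validated but no realised_value"
            )
        return problems


@dataclass
class Participant:
    """A study participant; metadata columns are carried through untouched."""

    participant_id: str
    group_id: str | None = None
    withdrew_after_round1: bool = False
    metadata: dict[str, Any] = field(default_factory=dict)


@dataclass
class RawJudgement:
    """A participant's four-step answer for one question and round.

    ``confidence_raw`` is the stated confidence, in percent in (0, 100],
    that the truth lies in [lower_raw, upper_raw].
    """

    participant_id: str
    question_id: str
    round: int
    lower_raw: float
    best_raw: float
    upper_raw: float
    confidence_raw: float
    comment: str = ""

    def check(self, question: Question | None = None) -> list[str]:
        problems = []
        tag = f"judgement ({self.participant_id}, {self.question_id}, r{self.round})"
        if self.round not in (1, 2):
            problems.append(f"{tag}: round must be 1 or 2")
        if not self.lower_raw <= self.best_raw <= self.upper_raw:
            problems.append(f"{tag}: lower ≤ best ≤ upper violated")
        if not 0 < self.confidence_raw <= 100:
            problems.append(f"{tag}: confidence_pct must be in (0, 100]")
        if question is not None:
            lo, hi = question.domain_min, question.domain_max
            if not (lo <= self.lower_raw and self.upper_raw <= hi):
                problems.append(f"{tag}: bounds outside question domain [{lo}, {hi}]")
        return problems


@dataclass
class StandardJudgement:
    """A raw judgement linearly rescaled to a common target confidence.

    The best estimate is never altered; bounds are extrapolated by the
    ratio target/stated and truncated to the question domain, with flags
    recording whether truncation occurred.
    """

    participant_id: str
    question_id: str
    round: int
    lower_std: float
    best_std: float
    upper_std: float
    target_confidence: float
    truncated_low: bool = False
    truncated_high: bool = False


# Column order of the standardised-judgement frame produced by
# interval standardisation; kept here so every module agrees on it.
STD_COLUMNS = [
    "participant_id",
    "question_id",
    "round",
    "lower_std",
    "best_std",
    "upper_std",
    "target_confidence",
    "truncated_low",
    "truncated_high",
]


@dataclass
class ElicitationDataset:
    """Questions, participants and raw judgements, validated together."""

    questions: list[Question]
    participants: list[Participant]
    judgements: list[RawJudgement]

    def question_map(self) -> dict[str, Question]:
        return {q.question_id: q for q in self.questions}

    def participant_map(self) -> dict[str, Participant]:
        return {p.participant_id: p for p in self.participants}

    def validate(self) -> None:
        """Check every dataset invariant; raise ValidationError listing all violations."""
        problems: list[str] = []
        qmap: dict[str, Question] = {}
        for q in self.questions:
            if q.question_id in qmap:
                problems.append(f"question {q.question_id}: duplicate question_id")
            qmap[q.question_id] = q
            problems.extend(q.check())
        pmap: dict[str, Participant] = {}
        for p in self.participants:
            if p.participant_id in pmap:
                problems.append(
                    f"participant {p.participant_id}: duplicate participant_id"
                )
            pmap[p.participant_id] = p
        seen: set[tuple[str, str, int]] = set()
        for j in self.judgements:
            tag = f"judgement ({j.participant_id}, {j.question_id}, r{j.round})"
            q = qmap.get(j.question_id)
            if q is None:
                problems.append(f"{tag}: unknown question_id")
            p = pmap.get(j.participant_id)
            if p is None:
                problems.append(f"{tag}: unknown participant_id")
            elif j.round == 2 and p.withdrew_after_round1:
                problems.append(f"{tag}: round-2 judgement from withdrawn participant")
            key = (j.participant_id, j.question_id, j.round)
            if key in seen:
                problems.append(f"{tag}: duplicate (participant, question, round)")
            seen.add(key)
            problems.extend(j.check(q))
        if problems:
            raise ValidationError("dataset failed validation", problems)

    # ---- frame views used by the vectorised pipeline stages ----

    def judgements_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    j.participant_id,
                    j.question_id,
                    j.round,
                    j.lower_raw,
                    j.best_raw,
                    j.upper_raw,
                    j.confidence_raw,
                    j.comment,
                )
                for j in self.judgements
            ],
            columns=[
                "participant_id",
                "question_id",
                "round",
                "lower",
                "best",
                "upper",
                "confidence_pct",
                "comment",
            ],
        )

    def questions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    q.question_id,
                    q.topic,
                    q.domain_min,
                    q.domain_max,
                    q.grain_size,
                    q.realised_value,
                    q.validated,
                )
                for q in self.questions
            ],
            columns=[
                "question_id",
                "topic",
                "domain_min",
                "domain_max",
                "grain_size",
                "realised_value",
                "validated",
            ],
        )

    def participants_frame(self) -> pd.DataFrame:
        keys: list[str] = []
        for p in self.participants:
            for k in p.metadata:
                if k not in keys:
                    keys.append(k)
        rows = []
        for p in self.participants:
            row = {
                "participant_id": p.participant_id,
                "group_id": p.group_id,
                "withdrew_after_round1": p.withdrew_after_round1,
            }
            for k in keys:
                row[k] = p.metadata.get(k)
            rows.append(row)
        return pd.DataFrame(
            rows, columns=["participant_id", "group_id", "withdrew_after_round1", *keys]
        )


def withdrawn_ids(participants: Iterable[Participant]) -> set[str]:
    return {p.participant_id for p in participants if p.withdrew_after_round1}
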