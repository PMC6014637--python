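"""Performance scoring: accuracy (ALRE), calibration, informativeness.

Because the elicited quantities live on wildly different scales, best
estimates (and the realised truth) are first *range-coded* per question:

    coded = (value - pool_min) / (pool_max - pool_min)

where the pool is the set of best estimates from all participants for
that question across both rounds.  The coded truth may legitimately fall
outside [0, 1].

Accuracy is the average log-ratio error over the questions an entity
answered,

    ALRE = mean_n |log10((x_n + 1) / (b_n + 1))|

with x and b the coded truth and prediction; the +1 avoids log of zero
and the per-question term is bounded by log10(2) when both values lie
in the pool range.  Calibration is the proportion of an entity's
standardised intervals that contain the realised truth (ideal = target
confidence, 0.80 here).  Informativeness is the mean width of the
entity's standardised intervals relative to a per-question background
range — the widest standardised bounds given by any participant across
both rounds; lower is better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .model import Question

SCORE_COLUMNS = [
    "entity_id",
    "entity_type",
    "round",
    "alre",
    "calibration",
    "informativeness",
    "n_questions",
]


@dataclass
class RangeContext:
    """Per-question pool and background extrema used by the scores.

    The pool (best estimates) and background range (standardised bounds)
    are taken over *all participants and both rounds*; group aggregates
    and the realised truth never enter them.
    """

    question_id: str
    pool_min: float
    pool_max: float
    background_lower: float
    background_upper: float

    @property
    def background_width(self) -> float:
        return self.background_upper - self.background_lower


@dataclass
class ScoreCard:
    """An entity's three performance scores for one round."""

    entity_id: str
    entity_type: str
    round: int
    alre: float
    calibration: float
    informativeness: float
    n_questions: int


def build_range_contexts(
    std: pd.DataFrame, questions: Sequence[Question]
) -> dict[str, RangeContext]:
    """Compute pool and background extrema from individual standardised judgements.

    Questions with no judgements are skipped with a warning.
    """
    contexts: dict[str, RangeContext] = {}
    grouped = std.groupby("question_id")
    for q in questions:
        qid = q.question_id
        if qid not in grouped.groups:
            warnings.warn(f"question {qid}: no judgements; skipped", stacklevel=2)
            continue
        sub = grouped.get_group(qid)
        contexts[qid] = RangeContext(
            question_id=qid,
            pool_min=float(sub["best_std"].min()),
            pool_max=float(sub["best_std"].max()),
            background_lower=float(sub["lower_std"].min()),
            background_upper=float(sub["upper_std"].max()),
        )
    return contexts


def range_code(value: float, context: RangeContext) -> float:
    """Rescale a value by the pool extrema; may exceed [0, 1] for the truth."""
    span = context.pool_max - context.pool_min
    if span <= 0:
        raise DomainError(
            f"question {context.question_id}: degenerate pool "
            "(all best estimates identical); drop the question before scoring"
        )
    return (value - context.pool_min) / span


def alre(coded_predictions, coded_truths) -> float:
    """Average log-ratio error over questions; smaller is better."""
    b = np.asarray(coded_predictions, dtype=float)
    x = np.asarray(coded_truths, dtype=float)
    if b.shape != x.shape or b.size == 0:
        raise DomainError("predictions and truths must be nonempty and aligned")
    if np.any(b <= -1) or np.any(x <= -1):
        raise DomainError("range-coded value ≤ -1: log-ratio term undefined")
    return float(np.mean(np.abs(np.log10((x + 1.0) / (b + 1.0)))))


def calibration(lowers, uppers, truths) -> float:
    """Proportion of standardised intervals containing the truth (closed bounds)."""
    lo = np.asarray(lowers, dtype=float)
    hi = np.asarray(uppers, dtype=float)
    x = np.asarray(truths, dtype=float)
    if lo.size == 0:
        raise DomainError("calibration requires at least one answered question")
    return float(np.mean((lo <= x) & (x <= hi)))


def informativeness(lowers, uppers, background_widths) -> float:
    """Mean interval width relative to the background range; lower is better."""
    lo = np.asarray(lowers, dtype=float)
    hi = np.asarray(uppers, dtype=float)
    w = np.asarray(background_widths, dtype=float)
    if lo.size == 0:
        raise DomainError("informativeness requires at least one answered question")
    keep = w > 0
    if not keep.all():
        warnings.warn(
            "questions with zero background width excluded from informativeness",
            stacklevel=2,
        )
    if not keep.any():
        raise DomainError("no question has a positive background width")
    return float(np.mean((hi[keep] - lo[keep]) / w[keep]))


def _score_frame(
    frame: pd.DataFrame,
    entity_col: str,
    entity_type,
    questions: Mapping[str, Question],
    contexts: Mapping[str, RangeContext],
) -> pd.DataFrame:
    """Vectorised evaluation of the three scores for one judgement frame."""
    lower_col = "lower_std" if "lower_std" in frame.columns else "lower_agg"
    best_col = "best_std" if "best_std" in frame.columns else "best_agg"
    upper_col = "upper_std" if "upper_std" in frame.columns else "upper_agg"

    scoreable = {
        qid: q
        for qid, q in questions.items()
        if q.realised_value is not None and qid in contexts
    }
    sub = frame[frame["question_id"].isin(scoreable)].copy()
    if len(sub) == 0:
        return pd.DataFrame(columns=SCORE_COLUMNS)
    degenerate = [
        qid
        for qid in sub["question_id"].unique()
        if contexts[qid].pool_max - contexts[qid].pool_min <= 0
    ]
    if degenerate:
        raise DomainError(
            "degenerate pool (all best estimates identical) for question(s) "
            + ", ".join(sorted(degenerate))
            + "; drop them before scoring"
        )
    qinfo = pd.DataFrame(
        {
            "question_id": list(scoreable),
            "truth": [scoreable[qid].realised_value for qid in scoreable],
            "pool_min": [contexts[qid].pool_min for qid in scoreable],
            "pool_span": [
                contexts[qid].pool_max - contexts[qid].pool_min for qid in scoreable
            ],
            "bg_width": [contexts[qid].background_width for qid in scoreable],
        }
    )
    sub = sub.merge(qinfo, on="question_id", how="left", validate="many_to_one")
    coded_b = (sub[best_col] - sub["pool_min"]) / sub["pool_span"]
    coded_x = (sub["truth"] - sub["pool_min"]) / sub["pool_span"]
    if (coded_b <= -1).any() or (coded_x <= -1).any():
        raise DomainError("range-coded value ≤ -1: log-ratio term undefined")
    sub["alre_term"] = np.abs(np.log10((coded_x + 1.0) / (coded_b + 1.0)))
    sub["captured"] = (sub[lower_col] <= sub["truth"]) & (
        sub["truth"] <= sub[upper_col]
    )
    rel = (sub[upper_col] - sub[lower_col]) / sub["bg_width"]
    sub["rel_width"] = rel.where(sub["bg_width"] > 0)
    if (sub["bg_width"] <= 0).any():
        warnings.warn(
            "questions with zero background width excluded from informativeness",
            stacklevel=2,
        )
    out = (
        sub.groupby([entity_col, "round"], as_index=False)
        .agg(
            alre=("alre_term", "mean"),
            calibration=("captured", "mean"),
            informativeness=("rel_width", "mean"),
            n_questions=("question_id", "size"),
        )
        .rename(columns={entity_col: "entity_id"})
    )
    out["entity_type"] = (
        out["entity_id"].map(entity_type) if callable(entity_type) else entity_type
    )
    return out[SCORE_COLUMNS]


def score_entities(
    individual_std: pd.DataFrame,
    group_judgements: pd.DataFrame | None,
    questions: Sequence[Question],
    contexts: Mapping[str, RangeContext] | None = None,
) -> pd.DataFrame:
    """One score card per entity per round.

    Individuals are scored on their own standardised judgements; groups
    (including the super group) on their aggregated judgements, with the
    same formulas and the same individual-derived range contexts.
    Questions without a realised value are excluded from all three
    scores; an entity with no scoreable question is skipped with a
    warning.
    """
    qmap = {q.question_id: q for q in questions}
    if contexts is None:
        contexts = build_range_contexts(individual_std, questions)
    frames = [
        _score_frame(individual_std, "participant_id", "individual", qmap, contexts)
    ]
    if group_judgements is not None and len(group_judgements):
        frames.append(
            _score_frame(
                group_judgements,
                "group_id",
                lambda gid: "super_group" if gid == "super_group" else "group",
                qmap,
                contexts,
            )
        )
    scores = pd.concat(frames, ignore_index=True)
    if len(scores) == 0:
        warnings.warn("no entity had a scoreable question", stacklevel=2)
    n_entities_in = individual_std["participant_id"].nunique() + (
        group_judgements["group_id"].nunique()
        if group_judgements is not None and len(group_judgements)
        else 0
    )
    if scores["entity_id"].nunique() < n_entities_in:
        warnings.warn(
            "entities with zero scoreable questions were skipped", stacklevel=2
        )
    return scores.sort_values(["entity_type", "entity_id", "round"]).reset_index(
        drop=True
    )
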