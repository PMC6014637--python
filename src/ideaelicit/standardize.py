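"""Credible-interval standardisation by linear extrapolation.

Each four-step answer comes with a stated confidence m' (percent) that
the truth lies between the elicited bounds.  To compare intervals across
participants they are rescaled to a common target confidence j (80% by
default) by scaling each half-interval by the ratio j/m', leaving the
best estimate untouched:

    lower_std = b' - (b' - l') * (j / m')
    upper_std = b' + (u' - b') * (j / m')

A stated confidence above the target shrinks the interval; below the
target widens it.  Bounds pushed past the question's feasible domain
(e.g. below zero for a density) are truncated to the domain edge and
flagged, so feedback documents can show participants what happened.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError
from .model import (
    STD_COLUMNS,
    ElicitationDataset,
    Question,
    RawJudgement,
    StandardJudgement,
)


def standardize_interval(
    judgement: RawJudgement, question: Question, target_confidence: float = 80.0
) -> StandardJudgement:
    """Rescale one raw interval to ``target_confidence`` percent.

    Parameters
    ----------
    judgement : RawJudgement
        The four-step answer; ``confidence_raw`` must be positive.
    question : Question
        Supplies the domain bounds used for truncation.
    target_confidence : float
        Target confidence j in percent, in (0, 100].

    Returns
    -------
    StandardJudgement
        Standardised bounds with truncation flags; the best estimate is
        carried through unchanged.
    """
    if judgement.confidence_raw <= 0:
        raise DomainError("confidence_raw must be > 0")
    if not 0 < target_confidence <= 100:
        raise DomainError("target_confidence must be in (0, 100]")
    factor = target_confidence / judgement.confidence_raw
    b = judgement.best_raw
    lower = b - (b - judgement.lower_raw) * factor
    upper = b + (judgement.upper_raw - b) * factor
    truncated_low = lower < question.domain_min
    truncated_high = upper > question.domain_max
    if truncated_low:
        lower = question.domain_min
    if truncated_high:
        upper = question.domain_max
    return StandardJudgement(
        participant_id=judgement.participant_id,
        question_id=judgement.question_id,
        round=judgement.round,
        lower_std=lower,
        best_std=b,
        upper_std=upper,
        target_confidence=target_confidence,
        truncated_low=bool(truncated_low),
        truncated_high=bool(truncated_high),
    )


def standardize_all(
    dataset: ElicitationDataset, target_confidence: float = 80.0
) -> pd.DataFrame:
    """Standardise every judgement in the dataset.

    Returns a frame with one row per raw judgement (same keying), with
    columns ``participant_id, question_id, round, lower_std, best_std,
    upper_std, target_confidence, truncated_low, truncated_high``.
    """
    if not 0 < target_confidence <= 100:
        raise DomainError("target_confidence must be in (0, 100]")
    jf = dataset.judgements_frame()
    if len(jf) == 0:
        return pd.DataFrame(columns=STD_COLUMNS)
    if (jf["confidence_pct"] <= 0).any():
        raise DomainError("confidence_raw must be > 0 for all judgements")
    qf = dataset.questions_frame()[["question_id", "domain_min", "domain_max"]]
    merged = jf.merge(qf, on="question_id", how="left", validate="many_to_one")
    factor = target_confidence / merged["confidence_pct"].to_numpy()
    b = merged["best"].to_numpy()
    lower = b - (b - merged["lower"].to_numpy()) * factor
    upper = b + (merged["upper"].to_numpy() - b) * factor
    dmin = merged["domain_min"].to_numpy()
    dmax = merged["domain_max"].to_numpy()
    trunc_low = lower < dmin
    trunc_high = upper > dmax
    lower = np.where(trunc_low, dmin, lower)
    upper = np.where(trunc_high, dmax, upper)
    out = pd.DataFrame(
        {
            "participant_id": merged["participant_id"],
            "question_id": merged["question_id"],
            "round": merged["round"],
            "lower_std": lower,
            "best_std": b,
            "upper_std": upper,
            "target_confidence": target_confidence,
            "truncated_low": trunc_low,
            "truncated_high": trunc_high,
        }
    )
    return out[STD_COLUMNS]
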