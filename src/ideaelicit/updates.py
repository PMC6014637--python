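"""Round-1 → Round-2 update analysis with grain sizes.

Accuracy scores are relative, so to judge whether a revision mattered
each question carries a *grain size*: a threshold in question units
(taken in practice from the standard error of prior data or a
management threshold) above which a change in a best estimate is deemed
consequential.  For each entity and question the change in distance to
the realised truth,

    delta_accuracy = |b1 - x| - |b2 - x|   (positive = improved),

is classified as improved / worsened / unchanged, flagged as meaningful
when |delta_accuracy| ≥ grain_size, and summarised per entity as the
proportion of updated questions on which accuracy improved (a value
below 0.5 means revisions hurt more often than they helped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .model import Question

UPDATE_COLUMNS = [
    "entity_id",
    "question_id",
    "changed_best",
    "changed_interval",
    "delta_accuracy",
    "meaningful",
    "direction",
]

SUMMARY_COLUMNS = [
    "entity_id",
    "n_best_updates",
    "n_interval_updates",
    "n_improved",
    "n_worsened",
    "n_meaningful_improved",
    "n_meaningful_worsened",
    "prop_improved_of_updated",
]


@dataclass
class UpdateRecord:
    """Classification of one entity's Round-1 → Round-2 change on one question."""

    entity_id: str
    question_id: str
    changed_best: bool
    changed_interval: bool
    delta_accuracy: float
    meaningful: bool
    direction: str  # improved | worsened | unchanged


@dataclass
class UpdateSummary:
    entity_id: str
    n_best_updates: int
    n_interval_updates: int
    n_improved: int
    n_worsened: int
    n_meaningful_improved: int
    n_meaningful_worsened: int
    prop_improved_of_updated: float | None


def _bounds(judgement) -> tuple[float, float, float]:
    """Accept individual (…_std) or group (…_agg) judgement records."""
    for lo, b, hi in (
        ("lower_std", "best_std", "upper_std"),
        ("lower_agg", "best_agg", "upper_agg"),
        ("lower", "best", "upper"),
    ):
        if hasattr(judgement, lo):
            return (
                float(getattr(judgement, lo)),
                float(getattr(judgement, b)),
                float(getattr(judgement, hi)),
            )
    raise DomainError("judgement object has no recognisable bound attributes")


def classify_update(r1, r2, question: Question, entity_id: str = "") -> UpdateRecord:
    """Classify one entity's change on one question between rounds.

    Exact equality decides whether the best estimate changed — elicited
    values are human-entered decimals, so no epsilon is applied.  A tie
    in distance to the truth (including an unchanged best) is classified
    ``unchanged``, keeping improved/worsened a partition of the strict
    changes.
    """
    if question.realised_value is None:
        raise DomainError(
            f"question {question.question_id} has no realised value; "
            "accuracy changes are undefined"
        )
    lo1, b1, hi1 = _bounds(r1)
    lo2, b2, hi2 = _bounds(r2)
    x = question.realised_value
    changed_best = b1 != b2
    changed_interval = (lo1 != lo2) or (hi1 != hi2)
    delta = abs(b1 - x) - abs(b2 - x)
    if not changed_best or delta == 0:
        direction = "unchanged"
    elif delta > 0:
        direction = "improved"
    else:
        direction = "worsened"
    meaningful = changed_best and abs(delta) >= question.grain_size
    return UpdateRecord(
        entity_id=entity_id or getattr(r1, "participant_id", getattr(r1, "group_id", "")),
        question_id=question.question_id,
        changed_best=changed_best,
        changed_interval=changed_interval,
        delta_accuracy=delta,
        meaningful=meaningful,
        direction=direction,
    )


def classify_updates(frame: pd.DataFrame, questions) -> pd.DataFrame:
    """Classify every entity × validated-question pair present in both rounds.

    ``frame`` is a standardised-judgement frame (individuals) or a group
    judgement frame; the entity column is inferred.  Questions without a
    realised value are excluded from all accuracy-change computations.
    """
    entity_col = "participant_id" if "participant_id" in frame.columns else "group_id"
    lower_col = "lower_std" if "lower_std" in frame.columns else "lower_agg"
    best_col = "best_std" if "best_std" in frame.columns else "best_agg"
    upper_col = "upper_std" if "upper_std" in frame.columns else "upper_agg"
    qmap = {q.question_id: q for q in questions}
    validated = {qid for qid, q in qmap.items() if q.realised_value is not None}

    sub = frame[frame["question_id"].isin(validated)]
    r1 = sub[sub["round"] == 1]
    r2 = sub[sub["round"] == 2]
    merged = r1.merge(
        r2,
        on=[entity_col, "question_id"],
        suffixes=("_1", "_2"),
        validate="one_to_one",
    )
    if len(merged) == 0:
        return pd.DataFrame(columns=UPDATE_COLUMNS)
    truth = merged["question_id"].map(lambda q: qmap[q].realised_value)
    grain = merged["question_id"].map(lambda q: qmap[q].grain_size)
    b1 = merged[f"{best_col}_1"]
    b2 = merged[f"{best_col}_2"]
    changed_best = b1 != b2
    changed_interval = (merged[f"{lower_col}_1"] != merged[f"{lower_col}_2"]) | (
        merged[f"{upper_col}_1"] != merged[f"{upper_col}_2"]
    )
    delta = (b1 - truth).abs() - (b2 - truth).abs()
    direction = np.where(
        ~changed_best | (delta == 0),
        "unchanged",
        np.where(delta > 0, "improved", "worsened"),
    )
    out = pd.DataFrame(
        {
            "entity_id": merged[entity_col],
            "question_id": merged["question_id"],
            "changed_best": changed_best,
            "changed_interval": changed_interval,
            "delta_accuracy": delta,
            "meaningful": changed_best & (delta.abs() >= grain),
            "direction": direction,
        }
    )
    return out.sort_values(["entity_id", "question_id"]).reset_index(drop=True)


def summarise_updates(records: pd.DataFrame) -> pd.DataFrame:
    """Per-entity update counts and the improved-of-updated proportion.

    Entities with no strict best-estimate change (improved + worsened
    = 0) get an undefined proportion, reported as NaN (empty in CSV).
    """
    if len(records) == 0:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    grouped = records.groupby("entity_id", as_index=False)
    out = grouped.agg(
        n_best_updates=("changed_best", "sum"),
        n_interval_updates=("changed_interval", "sum"),
        n_improved=("direction", lambda d: int((d == "improved").sum())),
        n_worsened=("direction", lambda d: int((d == "worsened").sum())),
    )
    meaningful = records[records["meaningful"]]
    for name, direction in (
        ("n_meaningful_improved", "improved"),
        ("n_meaningful_worsened", "worsened"),
    ):
        counts = (
            meaningful[meaningful["direction"] == direction]
            .groupby("entity_id")
            .size()
        )
        out[name] = out["entity_id"].map(counts).fillna(0).astype(int)
    denom = out["n_improved"] + out["n_worsened"]
    out["prop_improved_of_updated"] = np.where(
        denom > 0, out["n_improved"] / denom.replace(0, np.nan), np.nan
    )
    return out[SUMMARY_COLUMNS]


def median_update_counts(
    summaries: pd.DataFrame, n_boot: int = 10_000, seed: int = 0
) -> dict[str, dict[str, float]]:
    """Medians of per-entity update counts with bootstrap 95% intervals.

    The percentile bootstrap (``n_boot`` resamples, seeded) is applied
    to the cross-entity median of ``n_best_updates`` and
    ``n_interval_updates``.
    """
    if len(summaries) == 0:
        raise DomainError("no update summaries to summarise")
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, float]] = {}
    for col in ("n_best_updates", "n_interval_updates"):
        values = summaries[col].to_numpy(dtype=float)
        resamples = rng.integers(0, len(values), size=(n_boot, len(values)))
        boot_medians = np.median(values[resamples], axis=1)
        lo, hi = np.percentile(boot_medians, [2.5, 97.5])
        out[col] = {
            "median": float(np.median(values)),
            "ci_low": float(lo),
            "ci_high": float(hi),
        }
    return out
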