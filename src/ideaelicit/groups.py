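"""Group allocation, withdrawal policies, and quantile aggregation.

Group judgements are formed by quantile aggregation with the arithmetic
mean: the group's best estimate, lower bound and upper bound for a
question are the component-wise means of its members' standardised
values.  A virtual "super group" pools every retained participant.

Participants who withdraw after Round 1 are handled by policy:
``exclude`` removes them from the analysis and the aggregations of both
rounds; ``carry_forward_round1`` reuses their Round-1 judgements as
their Round-2 judgements.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .model import Participant, StandardJudgement, withdrawn_ids

SUPER_GROUP_ID = "super_group"

GROUP_COLUMNS = [
    "group_id",
    "question_id",
    "round",
    "lower_agg",
    "best_agg",
    "upper_agg",
    "n_members",
]


class WithdrawalPolicy(str, enum.Enum):
    """How to treat participants who withdrew after Round 1."""

    EXCLUDE = "exclude"
    CARRY_FORWARD_ROUND1 = "carry_forward_round1"


@dataclass
class GroupJudgement:
    """Arithmetic-mean aggregate of member judgements for one question/round."""

    group_id: str
    question_id: str
    round: int
    lower_agg: float
    best_agg: float
    upper_agg: float
    n_members: int


def allocate_groups(
    participants: Sequence[Participant | str], n_groups: int, seed: int
) -> dict[str, str]:
    """Randomly allocate participants to ``n_groups`` groups of near-equal size.

    Group sizes differ by at most one; remainder participants go to the
    first groups in shuffled order.  Deterministic given ``seed``.
    """
    ids = [p.participant_id if isinstance(p, Participant) else str(p) for p in participants]
    if not ids:
        raise DomainError("participants must be nonempty")
    if n_groups < 1:
        raise DomainError("n_groups must be ≥ 1")
    if n_groups > len(ids):
        raise DomainError(
            f"n_groups={n_groups} exceeds the number of participants ({len(ids)})"
        )
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    base, rem = divmod(len(ids), n_groups)
    mapping: dict[str, str] = {}
    pos = 0
    for g in range(n_groups):
        size = base + (1 if g < rem else 0)
        for pid in order[pos : pos + size]:
            mapping[pid] = f"G{g + 1}"
        pos += size
    return mapping


def aggregate_group(members: Iterable[StandardJudgement]) -> GroupJudgement:
    """Aggregate one group's judgements for a single (question, round)."""
    members = list(members)
    if not members:
        raise DomainError("cannot aggregate an empty member set")
    keys = {(m.question_id, m.round) for m in members}
    if len(keys) != 1:
        raise DomainError("members must share a single (question, round)")
    qid, rnd = keys.pop()
    return GroupJudgement(
        group_id="",
        question_id=qid,
        round=rnd,
        lower_agg=float(np.mean([m.lower_std for m in members])),
        best_agg=float(np.mean([m.best_std for m in members])),
        upper_agg=float(np.mean([m.upper_std for m in members])),
        n_members=len(members),
    )


def apply_withdrawal_policy(
    std: pd.DataFrame,
    participants: Sequence[Participant],
    policy: WithdrawalPolicy | str,
) -> pd.DataFrame:
    """Return the analysis set of standardised judgements under a policy.

    Under ``exclude`` every judgement (both rounds) of a withdrawn
    participant is dropped.  Under ``carry_forward_round1`` withdrawn
    participants keep their Round-1 rows and have them duplicated as
    Round-2 rows.
    """
    policy = WithdrawalPolicy(policy)
    gone = withdrawn_ids(participants)
    if not gone:
        return std.copy()
    if policy is WithdrawalPolicy.EXCLUDE:
        return std[~std["participant_id"].isin(gone)].reset_index(drop=True)
    carried = std[(std["participant_id"].isin(gone)) & (std["round"] == 1)].copy()
    carried["round"] = 2
    return pd.concat([std, carried], ignore_index=True)


def aggregate_all(
    std: pd.DataFrame,
    mapping: Mapping[str, str],
    participants: Sequence[Participant],
    policy: WithdrawalPolicy | str = WithdrawalPolicy.EXCLUDE,
) -> pd.DataFrame:
    """One group judgement per (group, question, round) admitted by the policy.

    Members who did not answer a question are simply absent from that
    question's mean, so ``n_members`` may vary across questions within a
    group.  A (group, question, round) with no admitted members yields
    no row.
    """
    admitted = apply_withdrawal_policy(std, participants, policy)
    unmapped = sorted(set(admitted["participant_id"]) - set(mapping))
    if unmapped:
        raise ValidationError(
            "participants present in judgements but missing from the group mapping",
            [f"participant {pid}: no group assigned" for pid in unmapped],
        )
    if len(admitted) == 0:
        return pd.DataFrame(columns=GROUP_COLUMNS)
    admitted = admitted.assign(
        group_id=admitted["participant_id"].map(mapping)
    )
    agg = (
        admitted.groupby(["group_id", "question_id", "round"], as_index=False)
        .agg(
            lower_agg=("lower_std", "mean"),
            best_agg=("best_std", "mean"),
            upper_agg=("upper_std", "mean"),
            n_members=("participant_id", "size"),
        )
        .sort_values(["group_id", "question_id", "round"], kind="mergesort")
        .reset_index(drop=True)
    )
    return agg[GROUP_COLUMNS]


def build_super_group(
    std: pd.DataFrame,
    participants: Sequence[Participant],
    policy: WithdrawalPolicy | str = WithdrawalPolicy.EXCLUDE,
) -> pd.DataFrame:
    """Aggregate every retained participant into one virtual group."""
    mapping = {
        p.participant_id: SUPER_GROUP_ID for p in participants
    }
    return aggregate_all(std, mapping, participants, policy)
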