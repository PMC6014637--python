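import math

import pytest

from ideaelicit import (
    ElicitationDataset,
    Participant,
    Question,
    RawJudgement,
    write_dataset,
)


def make_tiny_dataset() -> ElicitationDataset:
    """2 questions, 3 participants, 12 judgements (both rounds, all answered)."""
    questions = [
        Question("Q1", topic="starfish density", domain_min=0.0, domain_max=math.inf,
                 grain_size=0.22, realised_value=0.14, validated=True),
        Question("Q2", topic="bleached reefs", domain_min=0.0, domain_max=24.0,
                 grain_size=1.0, realised_value=6.0, validated=True),
    ]
    participants = [
        Participant("P1", group_id="G1", metadata={"gender": "f"}),
        Participant("P2", group_id="G1", metadata={"gender": "m"}),
        Participant("P3", group_id="G1", metadata={"gender": "f"}),
    ]
    judgements = []
    specs = {
        ("P1", "Q1"): (0.05, 0.2, 1.0, 80.0),
        ("P2", "Q1"): (0.5, 2.0, 10.0, 90.0),
        ("P3", "Q1"): (0.0, 0.1, 0.5, 50.0),
        ("P1", "Q2"): (2.0, 5.0, 10.0, 80.0),
        ("P2", "Q2"): (4.0, 8.0, 15.0, 100.0),
        ("P3", "Q2"): (1.0, 4.0, 9.0, 70.0),
    }
    for (pid, qid), (lo, b, hi, m) in specs.items():
        for rnd in (1, 2):
            shift = 0.0 if rnd == 1 else 0.1 * b
            judgements.append(
                RawJudgement(pid, qid, rnd, lo, b + shift, hi + shift,
                             confidence_raw=m, comment=f"{pid} view on {qid}")
            )
    ds = ElicitationDataset(questions, participants, judgements)
    ds.validate()
    return ds


@pytest.fixture
def tiny_dataset() -> ElicitationDataset:
    return make_tiny_dataset()


@pytest.fixture
def tiny_csvs(tmp_path, tiny_dataset):
    return write_dataset(tiny_dataset, tmp_path / "data")
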