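"""CSV readers and writers for elicitation datasets.

Three plain-text tables form the interchange format:

* ``questions.csv`` — question_id, topic, domain_min, domain_max,
  grain_size, realised_value (may be empty), validated (true/false).
  Empty domain cells encode an unbounded side (-inf / +inf).
* ``participants.csv`` — participant_id, group_id (may be empty),
  withdrew_after_round1 (true/false), plus arbitrary extra metadata
  columns preserved verbatim.
* ``judgements.csv`` — participant_id, question_id, round, lower, best,
  upper, confidence_pct, comment.

Numbers are written with Python ``repr`` so that read(write(d)) == d
bit-for-bit; parsing is locale-independent (decimal point only).
Confidence is a percent in (0, 100]; values ≤ 1 are rejected as likely
proportions rather than silently rescaled.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path

from .errors import SchemaError, ValidationError
from .model import ElicitationDataset, Participant, Question, RawJudgement

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}

QUESTION_COLUMNS = [
    "question_id",
    "topic",
    "domain_min",
    "domain_max",
    "grain_size",
    "realised_value",
    "validated",
]
PARTICIPANT_COLUMNS = ["participant_id", "group_id", "withdrew_after_round1"]
JUDGEMENT_COLUMNS = [
    "participant_id",
    "question_id",
    "round",
    "lower",
    "best",
    "upper",
    "confidence_pct",
    "comment",
]


def _read_rows(path: str | Path, required: list[str]) -> list[dict[str, str]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise SchemaError(
                f"{path.name}: missing required column(s): {', '.join(missing)}"
            )
        return list(reader)


def _parse_bool(text: str, where: str, problems: list[str]) -> bool:
    t = (text or "").strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    problems.append(f"{where}: cannot parse boolean {text!r}")
    return False


def _parse_float(text: str, where: str, problems: list[str]) -> float:
    try:
        return float(text)
    except (TypeError, ValueError):
        problems.append(f"{where}: cannot parse number {text!r}")
        return math.nan


def read_questions(path: str | Path) -> list[Question]:
    rows = _read_rows(path, QUESTION_COLUMNS)
    problems: list[str] = []
    out = []
    for i, row in enumerate(rows, start=1):
        where = f"questions row {i}"
        dmin = (row["domain_min"] or "").strip()
        dmax = (row["domain_max"] or "").strip()
        realised = (row["realised_value"] or "").strip()
        out.append(
            Question(
                question_id=row["question_id"],
                topic=row.get("topic") or "",
                domain_min=-math.inf if dmin == "" else _parse_float(dmin, where, problems),
                domain_max=math.inf if dmax == "" else _parse_float(dmax, where, problems),
                grain_size=_parse_float(row["grain_size"], where, problems),
                realised_value=None if realised == "" else _parse_float(realised, where, problems),
                validated=_parse_bool(row["validated"], where, problems),
            )
        )
    if problems:
        raise ValidationError("questions file failed validation", problems)
    return out


def read_participants(path: str | Path) -> list[Participant]:
    rows = _read_rows(path, PARTICIPANT_COLUMNS)
    problems: list[str] = []
    out = []
    for i, row in enumerate(rows, start=1):
        where = f"participants row {i}"
        meta = {k: v for k, v in row.items() if k not in PARTICIPANT_COLUMNS}
        gid = (row["group_id"] or "").strip()
        out.append(
            Participant(
                participant_id=row["participant_id"],
                group_id=gid or None,
                withdrew_after_round1=_parse_bool(
                    row["withdrew_after_round1"], where, problems
                ),
                metadata=meta,
            )
        )
    if problems:
        raise ValidationError("participants file failed validation", problems)
    return out


def read_judgements(path: str | Path) -> list[RawJudgement]:
    rows = _read_rows(path, JUDGEMENT_COLUMNS)
    problems: list[str] = []
    out = []
    for i, row in enumerate(rows, start=1):
        where = f"judgements row {i}"
        conf = _parse_float(row["confidence_pct"], where, problems)
        if not math.isnan(conf) and conf <= 1:
            problems.append(
                f"{where}: confidence_pct={conf} looks like a proportion; "
                "confidence must be a percent in (1, 100]"
            )
        try:
            rnd = int(row["round"])
        except (TypeError, ValueError):
            problems.append(f"{where}: cannot parse round {row['round']!r}")
            rnd = 0
        out.append(
            RawJudgement(
                participant_id=row["participant_id"],
                question_id=row["question_id"],
                round=rnd,
                lower_raw=_parse_float(row["lower"], where, problems),
                best_raw=_parse_float(row["best"], where, problems),
                upper_raw=_parse_float(row["upper"], where, problems),
                confidence_raw=conf,
                comment=row.get("comment") or "",
            )
        )
    if problems:
        raise ValidationError("judgements file failed validation", problems)
    return out


def read_dataset(
    questions_path: str | Path,
    participants_path: str | Path,
    judgements_path: str | Path,
) -> ElicitationDataset:
    """Read and fully validate the three-table dataset.

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValidationError
        If any row violates an invariant; the error lists every
        offending row.
    """
    dataset = ElicitationDataset(
        questions=read_questions(questions_path),
        participants=read_participants(participants_path),
        judgements=read_judgements(judgements_path),
    )
    dataset.validate()
    return dataset


def _fmt(value: float | None) -> str:
    if value is None:
        return ""
    if math.isinf(value):
        return ""
    return repr(float(value))


def _fmt_bool(value: bool) -> str:
    return "true" if value else "false"


def write_dataset(dataset: ElicitationDataset, directory: str | Path) -> dict[str, Path]:
    """Write the three CSVs; read_dataset on the result reproduces the input exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "questions": directory / "questions.csv",
        "participants": directory / "participants.csv",
        "judgements": directory / "judgements.csv",
    }
    with paths["questions"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(QUESTION_COLUMNS)
        for q in dataset.questions:
            w.writerow(
                [
                    q.question_id,
                    q.topic,
                    _fmt(q.domain_min),
                    _fmt(q.domain_max),
                    _fmt(q.grain_size),
                    _fmt(q.realised_value),
                    _fmt_bool(q.validated),
                ]
            )
    meta_keys: list[str] = []
    for p in dataset.participants:
        for k in p.metadata:
            if k not in meta_keys:
                meta_keys.append(k)
    with paths["participants"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PARTICIPANT_COLUMNS + meta_keys)
        for p in dataset.participants:
            w.writerow(
                [
                    p.participant_id,
                    p.group_id or "",
                    _fmt_bool(p.withdrew_after_round1),
                    *[p.metadata.get(k, "") for k in meta_keys],
                ]
            )
    with paths["judgements"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(JUDGEMENT_COLUMNS)
        for j in dataset.judgements:
            w.writerow(
                [
                    j.participant_id,
                    j.question_id,
                    j.round,
                    _fmt(j.lower_raw),
                    _fmt(j.best_raw),
                    _fmt(j.upper_raw),
                    _fmt(j.confidence_raw),
                    j.comment,
                ]
            )
    return paths
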