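"""Per-group feedback documents for the Delphi discussion phase.

After Round 1 each group receives a document showing, for every
question, the anonymised member intervals (standardised to the target
confidence), their best estimates, and the group mean, plotted on a
square-root-scaled axis (which spreads order-of-magnitude differences
without collapsing small values), together with a table of raw versus
standardised bounds so members can see the effect of standardisation
and truncation, and the compiled discussion comments.

Documents are self-contained HTML with inline SVG panels and are
byte-identical across renders of the same inputs (timestamps are
suppressed and the SVG hash salt is fixed).
"""

from __future__ import annotations

import html
import io as _io
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .model import Question

_SVG_OPTS = {"format": "svg", "metadata": {"Date": None}}


def _forward(x):
    return np.sign(x) * np.sqrt(np.abs(x))


def _inverse(x):
    return np.sign(x) * x**2


def anonymise_members(member_ids: Sequence[str]) -> dict[str, str]:
    """Stable anonymous codes: members sorted by identifier become P1, P2, …"""
    return {pid: f"P{i + 1}" for i, pid in enumerate(sorted(member_ids))}


def _question_panel_svg(
    sub: pd.DataFrame,
    agg_row,
    question: Question,
    codes: Mapping[str, str],
    sqrt_axis: bool,
) -> str:
    with plt.rc_context({"svg.hashsalt": "ideaelicit"}):
        fig, ax = plt.subplots(figsize=(6.0, 0.35 * (len(sub) + 2) + 1.0))
        sub = sub.sort_values("participant_id")
        labels, ys = [], []
        for y, row in enumerate(sub.itertuples()):
            ax.hlines(y, row.lower_std, row.upper_std, color="0.3", lw=1.5)
            ax.plot([row.best_std], [y], "o", color="black", ms=4)
            labels.append(codes[row.participant_id])
            ys.append(y)
        if agg_row is not None:
            y = len(sub) + 0.5
            ax.hlines(y, agg_row.lower_agg, agg_row.upper_agg, color="crimson", lw=2)
            ax.plot([agg_row.best_agg], [y], "o", color="crimson", ms=5)
            labels.append("Mean")
            ys.append(y)
        ax.set_yticks(ys, labels)
        ax.invert_yaxis()
        if sqrt_axis:
            ax.set_xscale("function", functions=(_forward, _inverse))
        ax.set_xlabel(
            f"{question.topic or question.question_id}"
            + (" (square-root axis)" if sqrt_axis else "")
        )
        ax.set_title(question.question_id, fontsize=10)
        fig.tight_layout()
        buf = _io.StringIO()
        fig.savefig(buf, **_SVG_OPTS)
        plt.close(fig)
    return buf.getvalue()


def _standardisation_table(
    raw: pd.DataFrame, std: pd.DataFrame, codes: Mapping[str, str]
) -> str:
    merged = raw.merge(
        std,
        on=["participant_id", "question_id", "round"],
        validate="one_to_one",
    ).sort_values(["question_id", "participant_id"])
    rows = []
    for r in merged.itertuples():
        flag = ""
        if r.truncated_low:
            flag += " low bound truncated"
        if r.truncated_high:
            flag += " high bound truncated"
        rows.append(
            "<tr>"
            + "".join(
                f"<td>{html.escape(str(v))}</td>"
                for v in (
                    r.question_id,
                    codes[r.participant_id],
                    f"{r.lower:g}",
                    f"{r.upper:g}",
                    f"{r.confidence_pct:g}%",
                    f"{r.lower_std:g}",
                    f"{r.upper_std:g}",
                    flag.strip() or "—",
                )
            )
            + "</tr>"
        )
    header = (
        "<tr><th>Question</th><th>Member</th><th>Raw lower</th><th>Raw upper</th>"
        "<th>Stated confidence</th><th>Std. lower</th><th>Std. upper</th>"
        "<th>Note</th></tr>"
    )
    return f"<table border='1' cellspacing='0' cellpadding='3'>{header}{''.join(rows)}</table>"


def make_feedback(
    std: pd.DataFrame,
    raw: pd.DataFrame,
    group_judgements: pd.DataFrame,
    mapping: Mapping[str, str],
    questions: Sequence[Question],
    outdir: str | Path,
    round: int = 1,
    sqrt_axis: bool = True,
    comments: pd.DataFrame | None = None,
) -> tuple[dict[str, Path], dict[str, str]]:
    """Render one feedback document per group for the given round.

    Returns the per-group file paths and the anonymisation map
    (participant_id -> anonymous code); the map is the caller's to log —
    it never appears in the documents themselves.

    Groups with no judgements in the round are skipped with a warning.
    """
    import warnings

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    std_r = std[std["round"] == round]
    raw_r = raw[raw["round"] == round]
    agg_r = group_judgements[group_judgements["round"] == round]
    qmap = {q.question_id: q for q in questions}
    codes_all: dict[str, str] = {}
    paths: dict[str, Path] = {}

    groups = sorted(set(mapping.values()))
    for gid in groups:
        members = sorted(pid for pid, g in mapping.items() if g == gid)
        gsub = std_r[std_r["participant_id"].isin(members)]
        if len(gsub) == 0:
            warnings.warn(f"group {gid}: no judgements; feedback skipped", stacklevel=2)
            continue
        codes = anonymise_members(members)
        codes_all.update(codes)
        panels = []
        for q in questions:
            qsub = gsub[gsub["question_id"] == q.question_id]
            arow = agg_r[
                (agg_r["group_id"] == gid) & (agg_r["question_id"] == q.question_id)
            ]
            agg_row = next(arow.itertuples(), None)
            if len(qsub) == 0:
                panels.append(
                    f"<h3>{q.question_id}</h3><p>No responses for this question.</p>"
                )
                continue
            svg = _question_panel_svg(qsub, agg_row, qmap[q.question_id], codes, sqrt_axis)
            panels.append(f"<h3>{html.escape(q.question_id)}</h3>{svg}")
        table = _standardisation_table(
            raw_r[raw_r["participant_id"].isin(members)], gsub, codes
        )
        comment_block = ""
        if comments is not None and len(comments):
            csub = comments[comments["participant_id"].isin(members)]
            items = "".join(
                f"<li><b>{html.escape(codes[r.participant_id])}</b> "
                f"({html.escape(str(r.question_id))}): {html.escape(str(r.comment))}</li>"
                for r in csub.itertuples()
                if str(r.comment).strip()
            )
            if items:
                comment_block = f"<h2>Comments</h2><ul>{items}</ul>"
        doc = (
            "<!DOCTYPE html><html><head><meta charset='utf-8'>"
            f"<title>Feedback — group {html.escape(gid)}, round {round}</title></head><body>"
            f"<h1>Group {html.escape(gid)} — Round {round} feedback</h1>"
            "<p>Intervals are standardised to the target confidence; circles mark "
            "best estimates and the red row is the group mean.</p>"
            + "".join(panels)
            + "<h2>Raw vs standardised bounds</h2>"
            + table
            + comment_block
            + "</body></html>"
        )
        path = outdir / f"feedback_{gid}_round{round}.html"
        path.write_text(doc, encoding="utf-8")
        paths[gid] = path
    return paths, codes_all
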