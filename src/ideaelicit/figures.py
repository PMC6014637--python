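"""Score-comparison figures.

Boxplots compare ALRE, calibration and informativeness across entity
types and rounds.  Notches are drawn at median ± 1.58·IQR/√n (the
conventional approximate 95% interval for a median) and the convention
is stated in each caption; per-entity scores are overlaid as dots.  A
round-1 vs round-2 scatter with the identity line shows individual
change.  Every number displayed is recomputable from ``scores.csv`` —
the figures perform no computation of their own beyond quartiles.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

_METRICS = ["alre", "calibration", "informativeness"]
_CAPTION = "Notches: median ± 1.58·IQR/√n. Dots: one per entity."


def _notched_box(ax, samples: list[np.ndarray], labels: list[str]) -> None:
    conf = []
    for s in samples:
        if len(s) == 0:
            conf.append((np.nan, np.nan))
            continue
        q1, med, q3 = np.percentile(s, [25, 50, 75])
        half = 1.58 * (q3 - q1) / np.sqrt(len(s))
        conf.append((med - half, med + half))
    ax.boxplot(
        samples,
        notch=True,
        conf_intervals=conf,
        tick_labels=labels,
        showfliers=False,
    )
    rng = np.random.default_rng(0)  # deterministic jitter
    for i, s in enumerate(samples, start=1):
        if len(s):
            ax.plot(
                i + rng.uniform(-0.12, 0.12, len(s)),
                s,
                "o",
                ms=3,
                alpha=0.5,
                color="tab:blue",
            )


def make_score_figures(
    scores: pd.DataFrame,
    outdir: str | Path,
    target_confidence: float = 80.0,
) -> list[Path]:
    """Render the metric boxplots and the round-1 vs round-2 scatter.

    Returns the written SVG paths.  Degenerate inputs (all entities
    identical) produce zero-height boxes without error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    cells = [
        (etype, rnd)
        for etype in scores["entity_type"].unique()
        for rnd in sorted(scores["round"].unique())
    ]
    with plt.rc_context({"svg.hashsalt": "ideaelicit"}):
        for metric in _METRICS:
            fig, ax = plt.subplots(figsize=(1.6 * max(len(cells), 2) + 1.5, 4.0))
            samples = [
                scores.loc[
                    (scores["entity_type"] == etype) & (scores["round"] == rnd), metric
                ]
                .dropna()
                .to_numpy()
                for etype, rnd in cells
            ]
            labels = [f"{etype}\nR{rnd}" for etype, rnd in cells]
            _notched_box(ax, samples, labels)
            if metric == "calibration":
                ax.axhline(
                    target_confidence / 100.0,
                    color="crimson",
                    ls="--",
                    lw=1,
                    label=f"target {target_confidence / 100.0:g}",
                )
                ax.legend(frameon=False, fontsize=8)
            ax.set_ylabel(metric)
            ax.set_title(f"{metric} by entity type and round", fontsize=10)
            fig.text(0.01, 0.01, _CAPTION, fontsize=7, color="0.4")
            fig.tight_layout(rect=(0, 0.04, 1, 1))
            path = outdir / f"scores_{metric}.svg"
            fig.savefig(path, format="svg", metadata={"Date": None})
            plt.close(fig)
            paths.append(path)

        rounds = sorted(scores["round"].unique())
        if len(rounds) >= 2:
            ind = scores[scores["entity_type"] == "individual"]
            wide = ind.pivot_table(
                index="entity_id", columns="round", values=_METRICS, aggfunc="first"
            )
            fig, axes = plt.subplots(1, 3, figsize=(11, 3.6))
            for ax, metric in zip(axes, _METRICS):
                if (metric, 1) not in wide.columns or (metric, 2) not in wide.columns:
                    ax.set_visible(False)
                    continue
                x = wide[(metric, 1)].to_numpy()
                y = wide[(metric, 2)].to_numpy()
                ax.plot(x, y, "o", ms=4, alpha=0.6)
                lims = [np.nanmin([x, y]), np.nanmax([x, y])]
                ax.plot(lims, lims, "-", color="0.5", lw=1)
                ax.set_xlabel(f"{metric} round 1")
                ax.set_ylabel(f"{metric} round 2")
            fig.suptitle("Individual change between rounds (identity line shown)", fontsize=10)
            fig.tight_layout()
            path = outdir / "scores_round1_vs_round2.svg"
            fig.savefig(path, format="svg", metadata={"Date": None})
            plt.close(fig)
            paths.append(path)
    return paths
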