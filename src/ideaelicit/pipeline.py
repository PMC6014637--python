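"""End-to-end pipeline driver.

Stages: standardise → allocate/aggregate (groups + super group) → score
→ update analysis → figures and feedback documents.  All tabular
outputs are CSV; a run log (JSON) captures the configuration, seeds,
software version and the anonymisation map.  Reruns with identical
inputs and seeds produce byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ElicitationError
from .feedback import make_feedback
from .figures import make_score_figures
from .groups import (
    WithdrawalPolicy,
    aggregate_all,
    allocate_groups,
    apply_withdrawal_policy,
    build_super_group,
)
from .io import read_dataset, write_dataset
from .model import ElicitationDataset
from .scoring import build_range_contexts, score_entities
from .simulate import SimulationConfig, simulate_study
from .standardize import standardize_all
from .updates import classify_updates, median_update_counts, summarise_updates

log = logging.getLogger("ideaelicit")


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    outdir: str = "run"
    target_confidence_pct: float = 80.0
    n_groups: int = 8
    allocation_seed: int = 0
    withdrawal_policy: str = "exclude"
    bootstrap_seed: int = 0
    questions_path: str | None = None
    participants_path: str | None = None
    judgements_path: str | None = None
    simulate: dict | None = None  # SimulationConfig fields; replaces the input paths
    make_figures: bool = True
    make_feedback_docs: bool = True
    sqrt_axis: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ElicitationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)


@contextmanager
def _stage(name: str):
    log.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:
        raise ElicitationError(f"stage '{name}' failed: {exc}") from exc
    log.info("stage %s: done", name)


def _load_or_simulate(config: PipelineConfig, outdir: Path) -> ElicitationDataset:
    if config.simulate is not None:
        sim = SimulationConfig(**config.simulate)
        dataset = simulate_study(sim)
        write_dataset(dataset, outdir / "inputs")
        return dataset
    if not (config.questions_path and config.participants_path and config.judgements_path):
        raise ElicitationError(
            "either the three input paths or a 'simulate' section must be configured"
        )
    return read_dataset(
        config.questions_path, config.participants_path, config.judgements_path
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and return the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": [],
    }

    with _stage("load"):
        dataset = _load_or_simulate(config, outdir)
        run_log["stages"].append("load")

    policy = WithdrawalPolicy(config.withdrawal_policy)

    with _stage("standardise"):
        std = standardize_all(dataset, config.target_confidence_pct)
        std.to_csv(outdir / "standardized.csv", index=False)
        run_log["stages"].append("standardise")

    with _stage("aggregate"):
        existing = {
            p.participant_id: p.group_id
            for p in dataset.participants
            if p.group_id is not None
        }
        if len(existing) == len(dataset.participants):
            mapping = existing
        else:
            mapping = allocate_groups(
                dataset.participants, config.n_groups, config.allocation_seed
            )
        analysis_std = apply_withdrawal_policy(std, dataset.participants, policy)
        groups_frame = aggregate_all(std, mapping, dataset.participants, policy)
        super_frame = build_super_group(std, dataset.participants, policy)
        all_groups = pd.concat([groups_frame, super_frame], ignore_index=True)
        all_groups.to_csv(outdir / "group_judgements.csv", index=False)
        run_log["stages"].append("aggregate")

    with _stage("score"):
        if not any(q.realised_value is not None for q in dataset.questions):
            raise ElicitationError("no validated questions")
        contexts = build_range_contexts(analysis_std, dataset.questions)
        scores = score_entities(analysis_std, all_groups, dataset.questions, contexts)
        scores.to_csv(outdir / "scores.csv", index=False)
        run_log["stages"].append("score")

    with _stage("updates"):
        ind_records = classify_updates(analysis_std, dataset.questions)
        ind_records.insert(1, "entity_type", "individual")
        grp_records = classify_updates(all_groups, dataset.questions)
        grp_records.insert(
            1,
            "entity_type",
            grp_records["entity_id"].map(
                lambda g: "super_group" if g == "super_group" else "group"
            ),
        )
        records = pd.concat([ind_records, grp_records], ignore_index=True)
        records.to_csv(outdir / "updates.csv", index=False)
        summary = summarise_updates(records[records["entity_type"] == "individual"])
        summary.to_csv(outdir / "update_summary.csv", index=False)
        if len(summary):
            medians = median_update_counts(summary, seed=config.bootstrap_seed)
            (outdir / "update_medians.json").write_text(
                json.dumps(medians, indent=2, sort_keys=True), encoding="utf-8"
            )
        run_log["stages"].append("updates")

    if config.make_figures:
        with _stage("figures"):
            make_score_figures(
                scores, outdir / "figures", config.target_confidence_pct
            )
            run_log["stages"].append("figures")

    if config.make_feedback_docs:
        with _stage("feedback"):
            raw = dataset.judgements_frame()
            comments = raw[["participant_id", "question_id", "round", "comment"]]
            _, anon_map = make_feedback(
                std,
                raw,
                groups_frame,
                mapping,
                dataset.questions,
                outdir / "feedback",
                round=1,
                sqrt_axis=config.sqrt_axis,
                comments=comments[comments["round"] == 1],
            )
            # The code <-> identifier map is confidential to the run log.
            run_log["anonymisation_map"] = anon_map
            run_log["stages"].append("feedback")

    (outdir / "run_log.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True), encoding="utf-8"
    )
    return outdir
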