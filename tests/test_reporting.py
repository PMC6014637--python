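import json
import re

import pandas as pd
import pytest
from click.testing import CliRunner

from ideaelicit import ElicitationError, PipelineConfig, run_pipeline
from ideaelicit.cli import main as cli_main


def _sim_config(outdir, seed=5, **overrides):
    sim = dict(seed=seed, n_experts=20, n_questions=6, n_groups=4)
    sim.update(overrides.pop("sim", {}))
    return PipelineConfig(
        outdir=str(outdir), n_groups=4, simulate=sim, **overrides
    )


class TestPipeline:
    def test_end_to_end_outputs_and_rerun_reproducibility(self, tmp_path):
        out1 = run_pipeline(_sim_config(tmp_path / "run1"))
        out2 = run_pipeline(_sim_config(tmp_path / "run2"))
        for name in ("standardized.csv", "group_judgements.csv", "scores.csv",
                     "updates.csv", "update_summary.csv"):
            a = (out1 / name).read_bytes()
            b = (out2 / name).read_bytes()
            assert a == b, f"{name} not byte-identical across reruns"
        log = json.loads((out1 / "run_log.json").read_text())
        assert "score" in log["stages"]
        assert (out1 / "figures").exists() and (out1 / "feedback").exists()

    def test_scores_cover_individuals_groups_and_super_group(self, tmp_path):
        out = run_pipeline(_sim_config(tmp_path / "run"))
        scores = pd.read_csv(out / "scores.csv")
        assert set(scores["entity_type"]) == {"individual", "group", "super_group"}
        assert set(scores["round"]) == {1, 2}
        assert (scores["alre"] >= 0).all()
        assert scores["calibration"].between(0, 1).all()

    def test_carry_forward_policy_keeps_withdrawn_in_round2(self, tmp_path):
        cfg_ex = _sim_config(tmp_path / "ex", withdrawal_policy="exclude",
                             sim={"p_withdraw": 0.4})
        cfg_cf = _sim_config(tmp_path / "cf", withdrawal_policy="carry_forward_round1",
                             sim={"p_withdraw": 0.4})
        out_ex = run_pipeline(cfg_ex)
        out_cf = run_pipeline(cfg_cf)
        g_ex = pd.read_csv(out_ex / "group_judgements.csv")
        g_cf = pd.read_csv(out_cf / "group_judgements.csv")
        sup_ex = g_ex[(g_ex.group_id == "super_group") & (g_ex["round"] == 2)]
        sup_cf = g_cf[(g_cf.group_id == "super_group") & (g_cf["round"] == 2)]
        assert (sup_cf["n_members"] > sup_ex["n_members"]).all()

    def test_no_validated_questions_aborts_scoring_stage(self, tmp_path, tiny_dataset):
        from ideaelicit import write_dataset

        for q in tiny_dataset.questions:
            q.realised_value = None
            q.validated = False
        paths = write_dataset(tiny_dataset, tmp_path / "data")
        cfg = PipelineConfig(
            outdir=str(tmp_path / "run"),
            questions_path=str(paths["questions"]),
            participants_path=str(paths["participants"]),
            judgements_path=str(paths["judgements"]),
            n_groups=1,
        )
        with pytest.raises(ElicitationError, match="no validated questions"):
            run_pipeline(cfg)


@pytest.fixture(scope="module")
def run_dir(tmp_path_factory):
    return run_pipeline(_sim_config(tmp_path_factory.mktemp("fb")))


class TestFeedbackDocuments:
    def test_one_document_per_group_with_one_panel_per_question(self, run_dir):
        docs = sorted((run_dir / "feedback").glob("feedback_*.html"))
        assert len(docs) == 4
        html = docs[0].read_text(encoding="utf-8")
        assert html.count("<h3>") == 6  # one panel per question

    def test_anonymisation_no_participant_ids_in_documents(self, run_dir):
        log = json.loads((run_dir / "run_log.json").read_text())
        anon = log["anonymisation_map"]
        for doc in (run_dir / "feedback").glob("*.html"):
            html = doc.read_text(encoding="utf-8")
            for pid in anon:
                assert pid not in html
        # the code<->identifier map is only in the run log
        assert all(re.fullmatch(r"P\d+", code) for code in anon.values())

    def test_feedback_documents_are_deterministic(self, tmp_path):
        out1 = run_pipeline(_sim_config(tmp_path / "a", make_figures=False))
        out2 = run_pipeline(_sim_config(tmp_path / "b", make_figures=False))
        docs1 = sorted((out1 / "feedback").glob("*.html"))
        docs2 = sorted((out2 / "feedback").glob("*.html"))
        for d1, d2 in zip(docs1, docs2):
            assert d1.read_bytes() == d2.read_bytes()

    def test_truncation_flag_visible_in_standardisation_table(self, tmp_path, tiny_dataset):
        from ideaelicit import write_dataset

        # P3 on Q1 states 50% -> widening past the zero floor
        paths = write_dataset(tiny_dataset, tmp_path / "data")
        cfg = PipelineConfig(
            outdir=str(tmp_path / "run"),
            questions_path=str(paths["questions"]),
            participants_path=str(paths["participants"]),
            judgements_path=str(paths["judgements"]),
            n_groups=1,
            make_figures=False,
        )
        out = run_pipeline(cfg)
        html = next((out / "feedback").glob("*.html")).read_text(encoding="utf-8")
        assert "low bound truncated" in html


class TestScoreFigures:
    def test_metric_panels_and_scatter_rendered(self, tmp_path):
        out = run_pipeline(_sim_config(tmp_path / "run", make_feedback_docs=False))
        figs = {p.name for p in (out / "figures").glob("*.svg")}
        assert {"scores_alre.svg", "scores_calibration.svg",
                "scores_informativeness.svg", "scores_round1_vs_round2.svg"} <= figs

    def test_degenerate_identical_entities_do_not_crash(self, tmp_path):
        from ideaelicit.figures import make_score_figures

        scores = pd.DataFrame(
            {
                "entity_id": [f"P{i}" for i in range(6)],
                "entity_type": ["individual"] * 6,
                "round": [1, 1, 1, 2, 2, 2],
                "alre": [0.1] * 6,
                "calibration": [0.8] * 6,
                "informativeness": [0.2] * 6,
                "n_questions": [5] * 6,
            }
        )
        paths = make_score_figures(scores, tmp_path)
        assert len(paths) == 4

    def test_box_median_matches_scores_csv(self, tmp_path):
        from matplotlib.cbook import boxplot_stats

        out = run_pipeline(_sim_config(tmp_path / "run", make_feedback_docs=False))
        scores = pd.read_csv(out / "scores.csv")
        sample = scores[(scores.entity_type == "individual") & (scores["round"] == 1)][
            "alre"
        ]
        # what matplotlib draws as the median line equals the CSV median
        drawn = boxplot_stats(sample.to_numpy())[0]["med"]
        assert drawn == pytest.approx(sample.median())


class TestCli:
    def test_simulate_then_full_stage_chain(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        res = runner.invoke(cli_main, [
            "simulate", "--seed", "4", "--experts", "12", "--questions", "5",
            "--groups", "3", "--out", str(data),
        ])
        assert res.exit_code == 0, res.output
        assert (data / "truths.csv").exists()
        args = ["--questions", str(data / "questions.csv"),
                "--participants", str(data / "participants.csv"),
                "--judgements", str(data / "judgements.csv")]
        std_csv = tmp_path / "std.csv"
        res = runner.invoke(cli_main, ["standardize", *args, "--out", str(std_csv)])
        assert res.exit_code == 0, res.output
        groups_csv = tmp_path / "groups.csv"
        res = runner.invoke(cli_main, ["aggregate", *args, "--out", str(groups_csv)])
        assert res.exit_code == 0, res.output
        scores_csv = tmp_path / "scores.csv"
        res = runner.invoke(cli_main, [
            "score", *args, "--group-judgements", str(groups_csv),
            "--out", str(scores_csv),
        ])
        assert res.exit_code == 0, res.output
        assert {"individual", "group", "super_group"} <= set(
            pd.read_csv(scores_csv)["entity_type"]
        )
        res = runner.invoke(cli_main, ["updates", *args,
                                       "--out", str(tmp_path / "upd.csv"),
                                       "--summary-out", str(tmp_path / "us.csv")])
        assert res.exit_code == 0, res.output

    def test_run_subcommand_with_yaml_config(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "outdir: {out}\nn_groups: 3\n"
            "simulate:\n  seed: 9\n  n_experts: 12\n  n_questions: 4\n  n_groups: 3\n"
            "make_figures: false\nmake_feedback_docs: false\n".format(
                out=tmp_path / "run"
            )
        )
        res = CliRunner().invoke(cli_main, ["run", "--config", str(cfg)])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "run" / "scores.csv").exists()
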