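import math
import warnings

import numpy as np
import pandas as pd
import pytest

from ideaelicit import (
    DomainError,
    Question,
    RangeContext,
    alre,
    build_range_contexts,
    calibration,
    informativeness,
    range_code,
    score_entities,
)


def _std_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["participant_id", "question_id", "round", "lower_std", "best_std", "upper_std"],
    )


class TestRangeContexts:
    def test_extrema_over_both_rounds(self):
        std = _std_frame(
            [
                ("P1", "Q1", 1, 0.0, 2.0, 5.0),
                ("P2", "Q1", 1, 1.0, 4.0, 12.0),
                ("P1", "Q1", 2, 0.5, 10.0, 11.0),
            ]
        )
        ctx = build_range_contexts(std, [Question("Q1", grain_size=1)])["Q1"]
        assert (ctx.pool_min, ctx.pool_max) == (2.0, 10.0)
        assert ctx.background_width == 12.0

    def test_question_without_judgements_is_skipped_with_warning(self):
        std = _std_frame([("P1", "Q1", 1, 0, 1, 2)])
        qs = [Question("Q1", grain_size=1), Question("Q2", grain_size=1)]
        with pytest.warns(UserWarning, match="Q2"):
            ctx = build_range_contexts(std, qs)
        assert set(ctx) == {"Q1"}

    def test_adding_a_judgement_outside_extrema_widens_the_context(self):
        rows = [("P1", "Q1", 1, 0.0, 2.0, 5.0), ("P2", "Q1", 1, 1.0, 4.0, 12.0)]
        base = build_range_contexts(_std_frame(rows), [Question("Q1", grain_size=1)])["Q1"]
        rows.append(("P3", "Q1", 2, -2.0, 15.0, 20.0))
        wider = build_range_contexts(_std_frame(rows), [Question("Q1", grain_size=1)])["Q1"]
        assert wider.pool_max > base.pool_max
        assert wider.background_width > base.background_width


class TestRangeCode:
    CTX = RangeContext("Q", pool_min=2.0, pool_max=10.0,
                       background_lower=0.0, background_upper=12.0)

    def test_endpoints_interior_and_outside(self):
        assert range_code(2.0, self.CTX) == 0.0
        assert range_code(10.0, self.CTX) == 1.0
        assert range_code(4.0, self.CTX) == pytest.approx(0.25)
        # the truth may legally fall outside the pool range
        assert range_code(12.0, self.CTX) == pytest.approx(1.25)

    def test_degenerate_pool_is_refused(self):
        ctx = RangeContext("Q", 3.0, 3.0, 0.0, 1.0)
        with pytest.raises(DomainError, match="degenerate"):
            range_code(5.0, ctx)


class TestScores:
    def test_alre_maximum_at_opposite_pool_endpoints(self):
        # coded truth 0, coded prediction 1 -> |log10(1/2)| = log10(2)
        assert alre([1.0], [0.0]) == pytest.approx(math.log10(2))
        assert alre([1.0], [0.0]) == pytest.approx(0.30103, abs=5e-6)

    def test_alre_zero_when_perfect_and_hand_example(self):
        assert alre([0.3, 0.7], [0.3, 0.7]) == 0.0
        got = alre([0.25, 0.2], [0.5, 0.2])
        assert got == pytest.approx((abs(math.log10(1.5 / 1.25)) + 0.0) / 2)
        assert got == pytest.approx(0.03959, abs=5e-6)

    def test_alre_guard_below_minus_one(self):
        with pytest.raises(DomainError):
            alre([-1.5], [0.0])

    def test_calibration_counts_inclusive_containment(self):
        lowers = np.zeros(13)
        uppers = np.ones(13)
        truths = np.array([0.5] * 9 + [2.0] * 4)
        assert calibration(lowers, uppers, truths) == pytest.approx(9 / 13)
        assert calibration(lowers, uppers, truths) == pytest.approx(0.6923, abs=5e-5)
        assert calibration([0.0], [1.0], [1.0]) == 1.0  # endpoint counts
        assert calibration(lowers, uppers, np.full(13, 0.5)) == 1.0

    def test_informativeness_extremes_and_mean(self):
        assert informativeness([0, 0], [10, 10], [10, 10]) == 1.0
        assert informativeness([3, 4], [3, 4], [10, 10]) == 0.0
        assert informativeness([0, 0], [2, 4], [10, 10]) == pytest.approx(0.3)

    def test_informativeness_excludes_zero_background_with_warning(self):
        with pytest.warns(UserWarning, match="zero background"):
            got = informativeness([0, 0], [2, 4], [10, 0])
        assert got == pytest.approx(0.2)


def _make_scoreable(n_participants=4, n_questions=5, seed=0):
    rng = np.random.default_rng(seed)
    questions = [
        Question(f"Q{q}", grain_size=1.0, realised_value=float(rng.uniform(0, 10)),
                 validated=True)
        for q in range(n_questions)
    ]
    rows = []
    for p in range(n_participants):
        for q in range(n_questions):
            for rnd in (1, 2):
                b = rng.uniform(0, 10)
                lo = b - rng.uniform(0.1, 5)
                hi = b + rng.uniform(0.1, 5)
                rows.append((f"P{p}", f"Q{q}", rnd, lo, b, hi))
    return questions, _std_frame(rows)


class TestScoreEntities:
    def test_identical_members_give_group_scorecard_equal_to_members(self):
        questions, _ = _make_scoreable()
        rows = []
        for p in range(3):
            for q in questions:
                rows.append((f"P{p}", q.question_id, 1, 1.0 + 0.1 * int(q.question_id[1]),
                             3.0, 6.0))
        # vary the pool with one extra distinct participant
        for q in questions:
            rows.append(("P9", q.question_id, 1, 0.0, 8.0, 9.0))
        std = _std_frame(rows)
        groups = pd.DataFrame(
            [("G1", q.question_id, 1, 1.0 + 0.1 * int(q.question_id[1]), 3.0, 6.0, 3)
             for q in questions],
            columns=["group_id", "question_id", "round", "lower_agg", "best_agg",
                     "upper_agg", "n_members"],
        )
        scores = score_entities(std, groups, questions)
        g = scores[scores["entity_type"] == "group"].iloc[0]
        m = scores[scores["entity_id"] == "P0"].iloc[0]
        for metric in ("alre", "calibration", "informativeness"):
            assert g[metric] == pytest.approx(m[metric], abs=1e-12)

    def test_unvalidated_questions_are_excluded_from_all_scores(self):
        questions, std = _make_scoreable(n_questions=5)
        questions[2].realised_value = None
        questions[2].validated = False
        scores = score_entities(std, None, questions)
        assert (scores["n_questions"] == 4).all()

    def test_brute_force_oracle_equivalence(self):
        """Vectorised scores equal a naive per-question loop to 1e-12."""
        questions, std = _make_scoreable(n_participants=6, n_questions=7, seed=3)
        contexts = build_range_contexts(std, questions)
        scores = score_entities(std, None, questions, contexts)
        for row in scores.itertuples():
            sub = std[(std["participant_id"] == row.entity_id) & (std["round"] == row.round)]
            terms, caps, widths = [], [], []
            for r in sub.itertuples():
                q = next(q for q in questions if q.question_id == r.question_id)
                c = contexts[r.question_id]
                cb = (r.best_std - c.pool_min) / (c.pool_max - c.pool_min)
                cx = (q.realised_value - c.pool_min) / (c.pool_max - c.pool_min)
                terms.append(abs(math.log10((cx + 1) / (cb + 1))))
                caps.append(r.lower_std <= q.realised_value <= r.upper_std)
                widths.append((r.upper_std - r.lower_std) / c.background_width)
            assert row.alre == pytest.approx(sum(terms) / len(terms), abs=1e-12)
            assert row.calibration == pytest.approx(sum(caps) / len(caps), abs=1e-12)
            assert row.informativeness == pytest.approx(sum(widths) / len(widths), abs=1e-12)
            assert row.n_questions == len(terms)

    def test_affine_invariance_of_all_three_scores(self):
        questions, std = _make_scoreable(seed=5)
        base = score_entities(std, None, questions)
        a, c = 3.7, -12.0
        questions2 = [
            Question(q.question_id, grain_size=q.grain_size * a,
                     realised_value=a * q.realised_value + c, validated=True)
            for q in questions
        ]
        std2 = std.copy()
        for col in ("lower_std", "best_std", "upper_std"):
            std2[col] = a * std2[col] + c
        mapped = score_entities(std2, None, questions2)
        for metric in ("alre", "calibration", "informativeness"):
            np.testing.assert_allclose(base[metric], mapped[metric], atol=1e-10)

    def test_alre_monotone_in_distance_to_truth(self):
        ctx = RangeContext("Q", 0.0, 10.0, 0.0, 10.0)
        truth_coded = range_code(4.0, ctx)
        errs = [alre([range_code(b, ctx)], [truth_coded]) for b in (9.0, 7.0, 5.0, 4.0)]
        assert errs == sorted(errs, reverse=True)
        assert errs[-1] == 0.0

    def test_degenerate_pool_refused_in_scoring(self):
        questions = [Question("Q1", grain_size=1, realised_value=5.0, validated=True)]
        std = _std_frame([("P1", "Q1", 1, 1, 3, 5), ("P2", "Q1", 1, 2, 3, 7)])
        with pytest.raises(DomainError, match="degenerate"):
            score_entities(std, None, questions)

    def test_per_question_term_bounded_by_log10_2_inside_pool(self):
        rng = np.random.default_rng(11)
        ctx = RangeContext("Q", 0.0, 1.0, 0.0, 1.0)
        for _ in range(200):
            b, x = rng.uniform(0, 1, 2)
            assert alre([b], [x]) <= math.log10(2) + 1e-12
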