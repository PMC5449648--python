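"""Contingency tables, Woolf intervals and batch screening."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.contingency_tables import Table2x2

from crowdscreen import (
    ALL_LABELS,
    OVERALL,
    CrowdModelConfig,
    DegenerateTableError,
    InvalidTableError,
    MissingQuestionError,
    QuestionPool,
    Question,
    TwoByTwoTable,
    UnknownAllergyError,
    build_table,
    odds_ratio,
    sample_cohort,
    screen_pool,
    screening_frame,
)
from conftest import make_response


def woolf_oracle(a, b, c, d, alpha=0.05):
    """Independent hand evaluation of the Woolf/Haldane formulas."""
    from scipy.stats import norm

    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_point = a * d / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(1 - alpha / 2)
    low = math.exp(math.log(or_point) - z * se)
    high = math.exp(math.log(or_point) + z * se)
    return or_point, low, high, corrected


class TestBuildTable:
    def test_one_record_per_cell(self, four_cell_responses):
        table = build_table(four_cell_responses, "asthma", "q1")
        assert table.cells == (1, 1, 1, 1)

    def test_unanswered_records_excluded(self, four_cell_responses):
        extra = [
            make_response("p5", {"q1": None}, {"asthma": True}),
            make_response("p6", {"q1": None}),
        ]
        table = build_table(four_cell_responses + extra, "asthma", "q1")
        assert table.cells == (1, 1, 1, 1)
        assert table.n_total == 4

    def test_overall_means_any_flag(self):
        responses = [
            make_response("p1", {"q1": "yes"}, {"food_allergy": True}),
            make_response("p2", {"q1": "yes"}),
            make_response("p3", {"q1": "no"}, {"pollinosis": True}),
            make_response("p4", {"q1": "no"}),
        ]
        assert build_table(responses, OVERALL, "q1").cells == (1, 1, 1, 1)

    def test_matches_bruteforce_tally_on_synthetic_cohort(self):
        """Counts equal an exhaustive per-record tally."""
        config = CrowdModelConfig(n_participants=20)
        pool = QuestionPool(active=[Question("q1", "k1", origin="seed")])
        rng = np.random.default_rng(7)
        cohort = sample_cohort(config, 1, None, pool, rng)
        for label in ALL_LABELS:
            a = b = c = d = 0
            answered = 0
            for r in cohort:
                ans = r.answers["q1"]
                if ans is None:
                    continue
                answered += 1
                case = r.is_case(label)
                if ans == "yes" and case:
                    a += 1
                elif ans == "yes":
                    b += 1
                elif case:
                    c += 1
                else:
                    d += 1
            if answered == 0:
                continue
            assert build_table(cohort, label, "q1").cells == (a, b, c, d)

    def test_unknown_label_rejected(self, four_cell_responses):
        with pytest.raises(UnknownAllergyError):
            build_table(four_cell_responses, "hayfever", "q1")

    def test_absent_question_rejected(self, four_cell_responses):
        with pytest.raises(MissingQuestionError):
            build_table(four_cell_responses, "asthma", "q99")


class TestOddsRatio:
    def test_balanced_table_is_null(self):
        res = odds_ratio(TwoByTwoTable(10, 10, 10, 10))
        assert res.or_point == pytest.approx(1.0)
        assert not res.significant
        assert not res.correction_applied

    def test_woolf_interval_direct_evaluation(self):
        # SE = sqrt(4/20 + 2/10) = sqrt(0.3) ~ 0.5477 on the log scale
        res = odds_ratio(TwoByTwoTable(20, 10, 10, 20))
        assert res.or_point == pytest.approx(4.0)
        assert res.ci_low == pytest.approx(1.367, abs=1e-3)
        assert res.ci_high == pytest.approx(11.703, abs=1e-3)
        assert res.significant

    def test_haldane_anscombe_correction(self):
        # corrected cells (5.5, 0.5, 10.5, 20.5) -> 112.75 / 5.25
        res = odds_ratio(TwoByTwoTable(5, 0, 10, 20))
        assert res.correction_applied
        assert res.or_point == pytest.approx(112.75 / 5.25)
        assert res.n_total == 35

    def test_degenerate_margins_rejected(self):
        with pytest.raises(DegenerateTableError):
            odds_ratio(TwoByTwoTable(0, 0, 5, 5))  # nobody exposed
        with pytest.raises(DegenerateTableError):
            odds_ratio(TwoByTwoTable(5, 5, 0, 0))  # nobody unexposed
        with pytest.raises(DegenerateTableError):
            odds_ratio(TwoByTwoTable(0, 5, 0, 5))  # no cases

    def test_invalid_cells_rejected(self):
        with pytest.raises(InvalidTableError):
            TwoByTwoTable(-1, 1, 1, 1)
        with pytest.raises(InvalidTableError):
            TwoByTwoTable(0, 0, 0, 0)

    def test_matches_statsmodels_on_uncorrected_tables(self, rng):
        """Independent cross-check of the logit interval."""
        for _ in range(50):
            a, b, c, d = rng.integers(1, 60, size=4)
            ours = odds_ratio(TwoByTwoTable(int(a), int(b), int(c), int(d)))
            ref = Table2x2(np.array([[a, b], [c, d]]))
            low, high = ref.oddsratio_confint(0.05)
            assert ours.or_point == pytest.approx(ref.oddsratio, rel=1e-10)
            assert ours.ci_low == pytest.approx(low, rel=1e-9)
            assert ours.ci_high == pytest.approx(high, rel=1e-9)

    @given(
        st.integers(1, 80), st.integers(1, 80),
        st.integers(1, 80), st.integers(1, 80),
    )
    def test_swapping_exposure_or_case_roles_inverts_or(self, a, b, c, d):
        base = odds_ratio(TwoByTwoTable(a, b, c, d))
        for swapped in (TwoByTwoTable(c, d, a, b), TwoByTwoTable(b, a, d, c)):
            inv = odds_ratio(swapped)
            assert inv.or_point == pytest.approx(1 / base.or_point, rel=1e-12)
            assert inv.ci_low == pytest.approx(1 / base.ci_high, rel=1e-9)
            assert inv.ci_high == pytest.approx(1 / base.ci_low, rel=1e-9)


class TestScreenPool:
    def test_singleton_matches_direct_composition(self, four_cell_responses):
        q = Question("q1", "k1", origin="seed")
        screening = screen_pool(four_cell_responses, [q], ["asthma"])
        direct = odds_ratio(build_table(four_cell_responses, "asthma", "q1"))
        assert screening.results == {("q1", "asthma"): direct}
        assert screening.skipped == []

    def test_full_cartesian_product(self):
        questions = [Question(f"q{i}", f"k{i}", origin="seed") for i in range(3)]
        responses = [
            make_response(f"p{i}", {q.question_id: "yes" if i % 2 else "no"
                                    for q in questions},
                          {"asthma": i % 3 == 0})
            for i in range(12)
        ]
        screening = screen_pool(responses, questions)
        assert len(screening.results) + len(screening.skipped) == 3 * 8

    def test_matches_per_pair_composition_on_cohort(self):
        """The vectorised tally equals build_table + odds_ratio per pair."""
        config = CrowdModelConfig(n_participants=80)
        pool = QuestionPool(
            active=[Question(f"q{i}", f"k{i}", origin="seed") for i in range(4)]
        )
        rng = np.random.default_rng(11)
        cohort = sample_cohort(config, 1, None, pool, rng)
        screening = screen_pool(cohort, pool.active)
        for (qid, label), res in screening.results.items():
            expected = odds_ratio(build_table(cohort, label, qid))
            assert res == expected
        for (qid, label), _reason in screening.skipped:
            with pytest.raises((DegenerateTableError, InvalidTableError)):
                odds_ratio(build_table(cohort, label, qid))

    def test_failed_pairs_reported_not_fatal(self):
        # q_bad is answered "yes" by everyone -> empty unexposed margin
        responses = [
            make_response(f"p{i}", {"q1": "yes" if i % 2 else "no",
                                    "q_bad": "yes"},
                          {"asthma": i % 3 == 0})
            for i in range(10)
        ]
        questions = [Question("q1", "k1"), Question("q_bad", "k2")]
        screening = screen_pool(responses, questions, ["asthma"])
        assert ("q1", "asthma") in screening.results
        assert [key for key, _ in screening.skipped] == [("q_bad", "asthma")]

    def test_null_factor_recovers_unit_or_at_large_n(self):
        """Monte-Carlo consistency: planted OR=1 -> empirical OR near 1."""
        config = CrowdModelConfig(n_participants=5000, nonresponse_rate=0.0)
        pool = QuestionPool(active=[Question("q1", "null_x", origin="seed")])
        cohort = sample_cohort(config, 1, None, pool,
                               np.random.default_rng(5))
        res = screen_pool(cohort, pool.active, [OVERALL]).results[
            ("q1", OVERALL)
        ]
        assert 0.8 < res.or_point < 1.25

    def test_screening_frame_layout(self, four_cell_responses):
        q = Question("q1", "concept_x", origin="seed")
        screening = screen_pool(four_cell_responses, [q], ["asthma"])
        frame = screening_frame(screening, [q])
        assert list(frame.columns) == [
            "question_id", "concept_key", "allergy_label",
            "a", "b", "c", "d", "or", "ci_low", "ci_high",
            "significant", "correction_applied",
        ]
        assert frame.iloc[0]["concept_key"] == "concept_x"


def test_significance_flag_equivalent_to_lower_bound_rule():
    """significant <=> ci_low > 1, exhaustively on a small-table grid."""
    for a in range(7):
        for b in range(7):
            for c in range(7):
                for d in range(7):
                    if min(a + b, c + d, a + c, b + d) == 0:
                        continue
                    res = odds_ratio(TwoByTwoTable(a, b, c, d))
                    o, lo, hi, corr = woolf_oracle(a, b, c, d)
                    assert res.or_point == pytest.approx(o, rel=1e-12)
                    assert res.ci_low == pytest.approx(lo, rel=1e-12)
                    assert res.ci_high == pytest.approx(hi, rel=1e-12)
                    assert res.correction_applied == corr
                    assert res.significant == (res.ci_low > 1.0)
                    assert res.ci_low <= res.or_point <= res.ci_high
                    assert math.isfinite(res.ci_low) and math.isfinite(res.ci_high)
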