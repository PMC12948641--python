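"""Cohort reconstruction: cumulative-percentage inversion, flag assignment, round trip."""

import pytest

from airwayscore import (
    InfeasibleAssignmentError,
    ScoreDistribution,
    assign_flag_vectors,
    build_contingency,
    check_flag_consistency,
    evaluate_predictors,
    mmc_reference,
    realize_records,
    reconstruct_cohort,
    score_counts_from_cumulative,
    study,
    study_score_distribution,
)
from airwayscore.reconstruct import _solve_binary_matrix


class TestCumulativeInversion:
    def test_difficult_group_counts(self):
        counts = score_counts_from_cumulative((79.3, 62.2, 36.6, 7.3, 0.0), 82)
        assert counts == (17, 14, 21, 24, 6, 0)

    def test_easy_group_counts(self):
        counts = score_counts_from_cumulative((28.8, 19.5, 3.4, 0.8, 0.0), 118)
        assert counts == (84, 11, 19, 3, 1, 0)

    def test_all_zero_cumulative_concentrates_at_score_zero(self):
        assert score_counts_from_cumulative((0.0,) * 5, 9) == (9, 0, 0, 0, 0, 0)

    def test_non_monotone_percentages_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            score_counts_from_cumulative((50.0, 60.0, 10.0, 0.0, 0.0), 82)

    def test_ambiguous_inversion_fails_the_re_rounding_self_check(self):
        # 50.0% of 3 rounds to 2, and 2/3 re-rounds to 66.7%, not 50.0%
        with pytest.raises(ValueError, match="re-rounds"):
            score_counts_from_cumulative((50.0, 0.0, 0.0, 0.0, 0.0), 3)


class TestFlagConsistency:
    def test_study_margins_balance(self, study_distribution):
        report = check_flag_consistency(study_distribution)
        assert report.passed
        assert report.difficult_from_histogram == report.difficult_from_marginals == 152
        assert report.easy_from_histogram == report.easy_from_marginals == 62

    def test_perturbed_marginal_breaks_the_balance(self, study_distribution):
        perturbed = dict(study.DIFFICULT_MARGINALS)
        perturbed["bmi"] += 1
        report = check_flag_consistency(study_distribution, difficult_marginals=perturbed)
        assert not report.passed
        assert report.difficult_from_marginals - report.difficult_from_histogram == 1


class TestFlagAssignment:
    def test_study_margins_are_reproduced_exactly(self, study_distribution):
        assignment = assign_flag_vectors(study_distribution, seed=1)
        dist = assignment.score_distribution()
        assert dist.counts_difficult == (17, 14, 21, 24, 6, 0)
        assert dist.counts_easy == (84, 11, 19, 3, 1, 0)
        assert assignment.column_sums("difficult") == study.DIFFICULT_MARGINALS
        assert assignment.column_sums("easy") == study.EASY_MARGINALS

    def test_single_patient_with_maximal_score_gets_all_flags(self):
        dist = ScoreDistribution((0, 0, 0, 0, 0, 1), (1, 0, 0, 0, 0, 0))
        marg5 = dict.fromkeys(study.PREDICTOR_TABLES, 1)
        marg0 = dict.fromkeys(study.PREDICTOR_TABLES, 0)
        assignment = assign_flag_vectors(dist, marg5, marg0, seed=0)
        assert assignment.difficult[0].as_tuple() == (1, 1, 1, 1, 1)

    def test_conservation_violation_is_reported_infeasible(self):
        dist = ScoreDistribution((0, 2, 0, 0, 0, 0), (1, 0, 0, 0, 0, 0))
        bad = dict.fromkeys(study.PREDICTOR_TABLES, 0)
        bad["bmi"], bad["tmd"] = 2, 1  # histogram demands 2 flags, marginals 3
        with pytest.raises(InfeasibleAssignmentError, match="conserved"):
            assign_flag_vectors(dist, bad, dict.fromkeys(study.PREDICTOR_TABLES, 0))

    def test_gale_ryser_infeasibility_detected_beyond_totals(self):
        # one row needing 2 distinct columns, but all demand in one column
        with pytest.raises(InfeasibleAssignmentError):
            _solve_binary_matrix([2, 0], [2, 0, 0, 0, 0])

    def test_deterministic_given_seed(self, study_distribution):
        a = assign_flag_vectors(study_distribution, seed=7)
        b = assign_flag_vectors(study_distribution, seed=7)
        c = assign_flag_vectors(study_distribution, seed=8)
        assert a == b
        assert a != c  # equal margins, different canonical patient ordering


class TestRealization:
    def test_round_trip_scoring_recovers_the_assignment(self, study_distribution):
        assignment = assign_flag_vectors(study_distribution, seed=3)
        records = realize_records(assignment, seed=3)
        rescored = tuple(evaluate_predictors(r) for r in records)
        assert rescored[: 82] == assignment.difficult
        assert rescored[82:] == assignment.easy
        references = [mmc_reference(r.mmc_class) for r in records]
        assert references == [True] * 82 + [False] * 118

    def test_realized_cohort_reproduces_published_composite_table(self, study_cohort):
        table = build_contingency(
            [evaluate_predictors(r).total >= 1 for r in study_cohort],
            [mmc_reference(r.mmc_class) for r in study_cohort],
        )
        assert table.as_tuple() == (65, 34, 17, 84)

    def test_realized_cohort_reproduces_published_ulbt_table(self, study_cohort):
        table = build_contingency(
            [evaluate_predictors(r).ulbt_flag for r in study_cohort],
            [mmc_reference(r.mmc_class) for r in study_cohort],
        )
        assert table.as_tuple() == (17, 6, 65, 112)

    def test_reconstruction_is_deterministic_given_seed(self):
        assert reconstruct_cohort(seed=11) == reconstruct_cohort(seed=11)
        assert reconstruct_cohort(seed=11) != reconstruct_cohort(seed=12)
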