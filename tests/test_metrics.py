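"""Contingency tables, diagnostic indices and Wilson confidence intervals."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from airwayscore import (
    ContingencyTable2x2,
    build_contingency,
    compute_metrics,
    evaluate_predictors,
    mmc_reference,
    proportion_ci,
    round_half_up,
    score_record,
)

tables = st.builds(
    ContingencyTable2x2,
    st.integers(0, 200), st.integers(0, 200), st.integers(0, 200), st.integers(1, 200),
)


def wilson_oracle(k, n, z=1.959963984540054):
    """Direct evaluation of the Wilson score interval formula."""
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return centre - half, centre + half


class TestBuildContingency:
    def test_composite_vs_reference_on_study_cohort(self, study_cohort):
        table = build_contingency(
            [score_record(r).positive for r in study_cohort],
            [mmc_reference(r.mmc_class) for r in study_cohort],
        )
        assert table.as_tuple() == (65, 34, 17, 84)

    def test_bmi_flag_vs_reference_on_study_cohort(self, study_cohort):
        table = build_contingency(
            [evaluate_predictors(r).bmi_flag for r in study_cohort],
            [mmc_reference(r.mmc_class) for r in study_cohort],
        )
        assert table.as_tuple() == (39, 9, 43, 109)

    def test_perfect_agreement_has_empty_discordant_cells(self):
        labels = [1, 0, 1, 1, 0]
        table = build_contingency(labels, labels)
        assert table.as_tuple() == (3, 0, 0, 2)

    def test_length_mismatch_and_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            build_contingency([1, 0], [1])
        with pytest.raises(ValueError, match="empty"):
            build_contingency([], [])


class TestComputeMetrics:
    def test_published_composite_indices(self, composite_table):
        m = compute_metrics(composite_table)
        assert round_half_up(m.sensitivity.percent, 2) == 79.27
        assert round_half_up(m.specificity.percent, 2) == 71.19
        assert round_half_up(m.ppv.percent, 2) == 65.66
        assert round_half_up(m.npv.percent, 2) == 83.17
        assert round_half_up(m.accuracy.percent, 2) == 74.50
        assert round_half_up(m.prevalence.percent, 0) == 41

    def test_published_single_predictor_indices(self):
        m = compute_metrics(ContingencyTable2x2(17, 6, 65, 112))
        assert round_half_up(m.sensitivity.percent, 2) == 20.73
        assert round_half_up(m.specificity.percent, 2) == 94.92

    def test_no_positive_predictions_leaves_ppv_undefined(self):
        m = compute_metrics(ContingencyTable2x2(0, 0, 7, 13))
        assert m.sensitivity.value == 0.0
        assert m.ppv is None
        assert m.npv is not None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 0, 5)

    @given(table=tables)
    def test_accuracy_identity(self, table):
        """accuracy == prevalence*sensitivity + (1-prevalence)*specificity, exactly."""
        m = compute_metrics(table)
        prev = m.prevalence.value
        sens = m.sensitivity.value if m.sensitivity else 0.0
        spec = m.specificity.value if m.specificity else 0.0
        assert m.accuracy.value == pytest.approx(
            prev * sens + (1 - prev) * spec, abs=1e-12
        )

    @given(table=tables, k=st.integers(2, 9))
    def test_metrics_invariant_under_cell_scaling(self, table, k):
        m1, mk = compute_metrics(table), compute_metrics(table.scaled(k))
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "prevalence"):
            a, b = getattr(m1, name), getattr(mk, name)
            if a is None:
                assert b is None
            else:
                assert a.value == pytest.approx(b.value, abs=1e-12)

    @given(table=tables)
    def test_prediction_relabelling_exchanges_cells(self, table):
        """Swapping the prediction labels maps tp<->fn, fp<->tn, so the
        relabelled sensitivity is 1 - the original sensitivity."""
        relabelled = ContingencyTable2x2(table.fn, table.tn, table.tp, table.fp)
        m, mr = compute_metrics(table), compute_metrics(relabelled)
        if m.sensitivity is not None:
            assert mr.sensitivity.value == pytest.approx(
                1 - m.sensitivity.value, abs=1e-12
            )


class TestWilsonInterval:
    def test_matches_direct_formula_for_study_sensitivity(self):
        est = proportion_ci(65, 82)
        low, high = wilson_oracle(65, 82)
        assert est.ci_low == pytest.approx(low, abs=1e-9)
        assert est.ci_high == pytest.approx(high, abs=1e-9)
        assert est.ci_low < 65 / 82 < est.ci_high
        assert est.ci_high - est.ci_low < 0.20  # narrower than +/-0.10

    @given(n=st.integers(1, 500), frac=st.floats(0, 1))
    def test_matches_direct_formula_and_stays_in_unit_interval(self, n, frac):
        k = round(frac * n)
        est = proportion_ci(k, n)
        low, high = wilson_oracle(k, n)
        assert est.ci_low == pytest.approx(low, abs=1e-9)
        assert est.ci_high == pytest.approx(high, abs=1e-9)
        assert 0.0 <= est.ci_low <= est.value <= est.ci_high <= 1.0

    def test_clopper_pearson_option_contains_wilson_point(self):
        wilson = proportion_ci(65, 82, method="wilson")
        exact = proportion_ci(65, 82, method="clopper-pearson")
        assert exact.ci_low < wilson.value < exact.ci_high
        # exact interval is at least as wide
        assert exact.ci_high - exact.ci_low >= wilson.ci_high - wilson.ci_low


@pytest.mark.parametrize(
    "value, decimals, expected",
    [(74.5, 1, 74.5), (0.745, 2, 0.75), (0.4890803, 3, 0.489), (5.666667, 2, 5.67)],
)
def test_round_half_up_ties_away_from_zero(value, decimals, expected):
    assert round_half_up(value, decimals) == expected
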