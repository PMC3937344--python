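"""NF-vs-reference-length calibration in equivalent base pairs."""

import pytest
from hypothesis import given, settings, strategies as st

from mfaquant import (
    ConditionNF,
    calibration_report,
    equivalent_bp_difference,
    fit_linear_nf_model,
    halving_ratio,
    matched_reference_length,
)
from mfaquant.errors import DegenerateModelError, InsufficientDataError, NoMatchError

from conftest import make_estimate


def paper_conditions():
    """The four fitted zinc-finger conditions (mean +/- SD) plus a zeroed pad."""
    return [
        ConditionNF("high_affinity", 20, make_estimate(0.65, 0.07, "high_affinity", 20)),
        ConditionNF("high_affinity", 40, make_estimate(0.32, 0.01, "high_affinity", 40)),
        ConditionNF("low_affinity", 20, make_estimate(0.39, 0.15, "low_affinity", 20)),
        ConditionNF("low_affinity", 40, make_estimate(0.20, 0.02, "low_affinity", 40)),
        ConditionNF("no_binding", 20,
                    make_estimate(0.0, None, "no_binding", 20, status="zeroed")),
    ]


class TestLinearModel:
    def test_two_point_line_through_published_means(self):
        model = fit_linear_nf_model([(20, 0.65), (40, 0.32)], "high_affinity")
        assert model.slope == pytest.approx(-0.0165, abs=1e-12)
        assert model.intercept == pytest.approx(0.98, abs=1e-12)
        # two-point models reproduce their fit points exactly
        assert model.predict(20) == pytest.approx(0.65, abs=1e-12)
        assert model.predict(40) == pytest.approx(0.32, abs=1e-12)

    def test_single_length_insufficient(self):
        with pytest.raises(InsufficientDataError):
            fit_linear_nf_model([(20, 0.5)])
        with pytest.raises(InsufficientDataError):
            fit_linear_nf_model([(20, 0.5), (20, 0.6)])

    def test_matched_length_inside_range(self):
        model = fit_linear_nf_model([(20, 0.65), (40, 0.32)])
        matched = matched_reference_length(model)
        assert matched.length_bp == pytest.approx((0.5 - 0.98) / -0.0165, rel=1e-9)
        assert matched.length_bp == pytest.approx(29.09, abs=0.01)
        assert not matched.extrapolated

    def test_matched_length_flags_extrapolation(self):
        model = fit_linear_nf_model([(20, 0.39), (40, 0.20)])
        matched = matched_reference_length(model)
        assert matched.length_bp == pytest.approx(8.42, abs=0.01)
        assert matched.extrapolated

    def test_fit_point_at_target_nf_returns_that_length(self):
        model = fit_linear_nf_model([(20, 0.5), (40, 0.25)])
        assert matched_reference_length(model).length_bp == pytest.approx(20.0)

    def test_zero_slope_is_degenerate(self):
        model = fit_linear_nf_model([(20, 0.5), (40, 0.5)])
        assert model.slope == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(DegenerateModelError):
            matched_reference_length(model)


class TestEquivalentBp:
    def test_matched_pair_on_published_table(self):
        res = equivalent_bp_difference(paper_conditions(), method="matched_pair")
        assert res.delta_bp == 20.0
        assert {res.motif_a, res.motif_b} == {"low_affinity", "high_affinity"}
        pair = {(c.motif_label, c.reference_n_bp) for c in res.detail}
        assert pair == {("low_affinity", 20), ("high_affinity", 40)}

    def test_linear_model_on_published_table(self):
        res = equivalent_bp_difference(paper_conditions(), method="linear_model")
        assert res.delta_bp == pytest.approx(20.67, abs=0.01)

    def test_methods_agree_within_two_bp(self):
        mp = equivalent_bp_difference(paper_conditions(), method="matched_pair")
        lm = equivalent_bp_difference(paper_conditions(), method="linear_model")
        assert abs(mp.delta_bp - lm.delta_bp) <= 2.0

    def test_identical_conditions_at_same_length_give_zero(self):
        conds = [
            ConditionNF("a", 20, make_estimate(0.4, 0.05, "a", 20)),
            ConditionNF("b", 20, make_estimate(0.4, 0.05, "b", 20)),
        ]
        assert equivalent_bp_difference(conds).delta_bp == 0.0

    def test_no_qualifying_pair_lists_gaps(self):
        conds = [
            ConditionNF("a", 20, make_estimate(0.8, 0.01, "a", 20)),
            ConditionNF("b", 40, make_estimate(0.2, 0.01, "b", 40)),
        ]
        with pytest.raises(NoMatchError, match="dNF"):
            equivalent_bp_difference(conds)

    def test_linear_model_requires_two_lengths_per_motif(self):
        conds = [
            ConditionNF("a", 20, make_estimate(0.6, 0.05, "a", 20)),
            ConditionNF("b", 20, make_estimate(0.5, 0.05, "b", 20)),
        ]
        with pytest.raises(InsufficientDataError):
            equivalent_bp_difference(conds, method="linear_model")

    def test_best_pair_has_smallest_mean_gap(self):
        conds = [
            ConditionNF("a", 20, make_estimate(0.40, 0.20, "a", 20)),
            ConditionNF("b", 30, make_estimate(0.55, 0.20, "b", 30)),
            ConditionNF("b", 40, make_estimate(0.41, 0.20, "b", 40)),
        ]
        res = equivalent_bp_difference(conds)
        assert res.delta_bp == 20.0  # pairs a@20 with b@40 (|dNF|=0.01)


class TestHalvingRatio:
    def test_published_ratios(self):
        assert halving_ratio([(20, 0.65), (40, 0.32)]) == pytest.approx(0.32 / 0.65)
        assert halving_ratio([(20, 0.39), (40, 0.20)]) == pytest.approx(0.20 / 0.39)

    @given(st.floats(0.1, 1.0), st.integers(5, 50))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_exact_halving_gives_half(self, nf, length):
        assert halving_ratio([(length, nf), (2 * length, nf / 2)]) == pytest.approx(0.5)

    def test_lengths_must_double(self):
        with pytest.raises(ValueError):
            halving_ratio([(20, 0.6), (50, 0.3)])


def test_calibration_report_contains_both_methods():
    estimates = [c.estimate for c in paper_conditions()]
    report = calibration_report(estimates)
    assert report["methods"]["matched_pair"]["delta_bp"] == 20.0
    assert report["methods"]["linear_model"]["delta_bp"] == pytest.approx(20.67, abs=0.01)
    zeroed = [c for c in report["conditions"] if c["status"] == "zeroed"]
    assert zeroed and zeroed[0]["nf_mean"] == 0.0
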