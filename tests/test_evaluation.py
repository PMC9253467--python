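"""Coefficient-of-determination forms and surrogate scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from leukotransit.bpnn import Network, NetworkSpec, SurrogateModel
from leukotransit.evaluation import (
    evaluate_surrogate,
    fit_correlation,
    r_squared,
    response_surface,
)


class TestRSquared:
    def test_perfect_fit_both_forms(self):
        y = np.array([1.0, 2.0, 5.0])
        assert r_squared(y, y, "standard") == pytest.approx(1.0)
        assert r_squared(y, y, "printed") == pytest.approx(1.0)

    def test_mean_predictor_scores_zero(self):
        true = np.array([1.0, 2.0, 3.0])
        pred = np.full(3, true.mean())
        assert r_squared(pred, true, "standard") == pytest.approx(0.0)
        assert r_squared(pred, true, "printed") == pytest.approx(0.0)

    def test_three_point_hand_calculation(self):
        # true = [1,2,3], pred = [1,2,4]: SS_res = 1, SS_tot = 2 -> 0.5;
        # printed: (pred - 2)^2 sums to 1+0+4 = 5 -> 5/2 = 2.5
        pred, true = [1.0, 2.0, 4.0], [1.0, 2.0, 3.0]
        assert r_squared(pred, true, "standard") == pytest.approx(0.5)
        assert r_squared(pred, true, "printed") == pytest.approx(2.5)

    def test_printed_form_can_exceed_one_for_biased_predictors(self):
        # the explained-variance ratio is unbounded; the standard form is not
        assert r_squared([1.0, 2.0, 4.0], [1.0, 2.0, 3.0], "printed") > 1.0
        assert r_squared([1.0, 2.0, 4.0], [1.0, 2.0, 3.0], "standard") <= 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            r_squared([1.0, 2.0], [3.0, 3.0])

    def test_unknown_form(self):
        with pytest.raises(ValueError, match="form"):
            r_squared([1.0, 2.0], [1.0, 2.0], "adjusted")

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    def test_affine_invariance_of_standard_form(self, a, b):
        rng = np.random.default_rng(11)
        true = rng.uniform(0, 1, 20)
        pred = true + 0.05 * rng.standard_normal(20)
        base = r_squared(pred, true)
        scaled = r_squared(a * pred + b, a * true + b)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_forms_agree_for_good_fits(self):
        rng = np.random.default_rng(5)
        true = rng.uniform(0, 1, 200)
        pred = true + 1e-3 * rng.standard_normal(200)
        std = r_squared(pred, true, "standard")
        assert std > 0.99
        assert abs(std - r_squared(pred, true, "printed")) < 1e-3


def _constant_model(value=0.25, arity=2):
    """Surrogate that predicts the same number everywhere."""
    cols = ["Re", "AR", "displacement"][:arity]
    sizes = [arity, 1]
    spec = NetworkSpec(layer_sizes=sizes, hidden_activation="purelin")
    net = Network([np.zeros((arity, 1))], [np.array([value])], spec)
    norm = {c: (0.0, 1.0) for c in cols}
    norm["transit_time"] = (-1.0, 1.0)
    return SurrogateModel(net, cols, "transit_time", norm)


def _linear_time_model():
    """Surrogate realizing an exact decreasing plane in (Re, AR)."""
    spec = NetworkSpec(layer_sizes=[2, 1], hidden_activation="purelin")
    net = Network([np.array([[-0.4], [-0.5]])], [np.array([0.0])], spec)
    norm = {"Re": (0.1, 0.2), "AR": (0.5, 0.95), "transit_time": (0.0, 1.0)}
    return SurrogateModel(net, ["Re", "AR"], "transit_time", norm)


class TestEvaluateSurrogate:
    def test_empty_case_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate_surrogate(_constant_model(), [])

    def test_schema_mismatch_rejected(self):
        model = _constant_model(arity=2)
        with pytest.raises(ValueError, match="schema"):
            evaluate_surrogate(model, [{"Re": 0.1, "AR": 0.8, "R_max": [1.0]}])

    def test_scalar_cases_pooled(self):
        model = _linear_time_model()
        cases = [
            {"Re": re, "AR": ar, "transit_time": float(model.predict(
                pd.DataFrame({"Re": [re], "AR": [ar]}))[0])}
            for re, ar in [(0.1, 0.5), (0.15, 0.7), (0.2, 0.95)]
        ]
        rep = evaluate_surrogate(model, cases)
        assert rep.pooled_r2 == pytest.approx(1.0)
        assert len(rep.per_case) == 3

    def test_report_is_pure_function(self):
        model = _linear_time_model()
        cases = [{"Re": 0.1, "AR": 0.6, "transit_time": 0.5},
                 {"Re": 0.2, "AR": 0.9, "transit_time": 0.1}]
        a = evaluate_surrogate(model, cases)
        b = evaluate_surrogate(model, cases)
        pd.testing.assert_frame_equal(a.per_case, b.per_case)
        assert a.pooled_r2 == b.pooled_r2


class TestResponseSurface:
    def test_constant_net_gives_flat_surface(self):
        surf = response_surface(_constant_model(), (0.05, 0.25), (0.4, 1.0), resolution=15)
        assert np.ptp(surf["surface"]) == pytest.approx(0.0, abs=1e-15)
        assert surf["frac_negative_slope_re"] == 0.0
        assert surf["frac_negative_slope_ar"] == 0.0

    def test_decreasing_plane_has_all_negative_slopes(self):
        surf = response_surface(_linear_time_model(), (0.1, 0.2), (0.5, 0.95), resolution=12)
        assert surf["frac_negative_slope_re"] == 1.0
        assert surf["frac_negative_slope_ar"] == 1.0
        assert not surf["extrapolated"].any()

    def test_extrapolation_flagged_not_fatal(self):
        surf = response_surface(_linear_time_model(), (0.0, 0.3), (0.3, 1.2), resolution=10)
        assert surf["extrapolated"].any()

    def test_motion_schema_rejected(self):
        with pytest.raises(ValueError, match="2-input"):
            response_surface(_constant_model(arity=3), (0.1, 0.2), (0.5, 0.95))


def test_fit_correlation_matches_numpy():
    rng = np.random.default_rng(1)
    a = rng.uniform(0, 1, 50)
    b = a + 0.1 * rng.standard_normal(50)
    assert fit_correlation(a, b) == pytest.approx(np.corrcoef(a, b)[0, 1])
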