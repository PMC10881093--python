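import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from beefdmi import (
    CowObservation,
    Dataset,
    evaluate_equation,
    generate_dataset,
    rmsd,
    theil_decomposition,
    unity_regression,
)
from beefdmi.evaluation import DegenerateDesignError, PerfectPredictionError
from conftest import scaled_config

from oracles import ols_normal_equations

O4 = np.array([11.0, 13.0, 14.0, 17.0])
P4 = np.array([10.0, 12.0, 14.0, 16.0])

vectors = st.lists(
    st.floats(5, 25, allow_nan=False), min_size=5, max_size=12
).filter(lambda v: max(v) - min(v) > 0.5)


class TestUnityRegression:
    def test_hand_checked_four_points(self):
        reg = unity_regression(O4, P4)
        assert reg.slope == pytest.approx(0.95)
        assert reg.intercept == pytest.approx(1.40)
        assert reg.r2 == pytest.approx(0.96267, abs=1e-5)
        assert reg.syx_rmse == pytest.approx(0.5916, abs=1e-4)

    def test_perfect_fit(self):
        reg = unity_regression(P4, P4)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)
        assert reg.slope == pytest.approx(1.0)
        assert reg.r2 == pytest.approx(1.0)
        assert reg.syx_rmse == pytest.approx(0.0, abs=1e-10)

    def test_doubled_observed_detects_slope(self, rng):
        p = rng.uniform(8, 20, size=200)
        reg = unity_regression(2 * p, p)
        assert reg.slope == pytest.approx(2.0)
        assert reg.p_slope_one < 1e-6
        assert reg.p_joint < 1e-6

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegenerateDesignError):
            unity_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            unity_regression([1.0, 2.0], [1.0, 2.0])

    def test_matches_normal_equations_oracle(self, rng):
        """OLS agrees with explicit matrix inversion on random 5-point sets."""
        for _ in range(20):
            p = rng.uniform(5, 25, size=5)
            o = rng.uniform(5, 25, size=5)
            a, b = ols_normal_equations(p, o)
            reg = unity_regression(o, p)
            assert reg.intercept == pytest.approx(a, abs=1e-8)
            assert reg.slope == pytest.approx(b, abs=1e-8)


class TestRmsd:
    def test_hand_checked(self):
        assert rmsd(O4, P4) == pytest.approx(np.sqrt(3 / 4))

    def test_zero_iff_identical(self):
        assert rmsd(P4, P4) == 0.0
        assert rmsd(P4 + 0.1, P4) > 0

    def test_single_pair(self):
        assert rmsd([10.0], [13.0]) == pytest.approx(3.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmsd([1.0, 2.0], [1.0])


class TestTheilDecomposition:
    def test_hand_checked_four_points(self):
        t = theil_decomposition(O4, P4)
        assert t.sspe == pytest.approx(3.00)
        assert t.u_bias_pct == pytest.approx(75.0)
        assert t.u_slope_pct == pytest.approx(100 * 0.05 / 3.0)
        assert t.u_error_pct == pytest.approx(100 * 0.70 / 3.0)

    def test_pure_shift_is_all_bias(self):
        t = theil_decomposition(P4 + 2.0, P4)
        assert t.u_bias_pct == pytest.approx(100.0)
        assert t.u_slope_pct == pytest.approx(0.0, abs=1e-9)
        assert t.u_error_pct == pytest.approx(0.0, abs=1e-9)

    def test_pure_disturbance_is_all_error(self):
        # residuals orthogonal to P with slope 1 and equal means
        p = np.array([10.0, 12.0, 14.0, 16.0])
        e = np.array([1.0, -1.0, -1.0, 1.0])  # mean 0, uncorrelated with p
        t = theil_decomposition(p + e, p)
        assert t.u_error_pct == pytest.approx(100.0)

    def test_perfect_prediction_flagged(self):
        with pytest.raises(PerfectPredictionError):
            theil_decomposition(P4, P4)

    @given(vectors, vectors)
    def test_components_sum_to_sspe(self, o, p):
        """The three components always recover SSPE to machine precision."""
        n = min(len(o), len(p))
        o, p = np.array(o[:n]), np.array(p[:n])
        if np.ptp(p) < 1e-6 or np.allclose(o, p):
            return
        t = theil_decomposition(o, p)
        assert t.u_bias_pct + t.u_slope_pct + t.u_error_pct == pytest.approx(100.0, abs=1e-9)
        parts = t.sspe * np.array([t.u_bias_pct, t.u_slope_pct, t.u_error_pct]) / 100
        assert parts.sum() == pytest.approx(np.sum((o - p) ** 2), rel=1e-12)

    @given(vectors, vectors, st.floats(-10, 10))
    def test_affine_shift_equivariance(self, o, p, c):
        """Shifting both series leaves slope, U_slope, and U_error unchanged."""
        n = min(len(o), len(p))
        o, p = np.array(o[:n]), np.array(p[:n])
        if np.ptp(p) < 1e-6 or np.allclose(o, p):
            return
        base = theil_decomposition(o, p)
        shifted = theil_decomposition(o + c, p + c)
        assert shifted.sspe == pytest.approx(base.sspe, rel=1e-9)
        assert shifted.u_slope_pct == pytest.approx(base.u_slope_pct, rel=1e-6, abs=1e-9)
        assert shifted.u_error_pct == pytest.approx(base.u_error_pct, rel=1e-6, abs=1e-9)
        b0 = unity_regression(o, p).slope if n >= 3 else None
        b1 = unity_regression(o + c, p + c).slope if n >= 3 else None
        assert b1 == pytest.approx(b0, rel=1e-9)

    @given(vectors, vectors)
    def test_sspe_dominates_residual_ss(self, o, p):
        """SSPE >= regression RSS, equal only when the fit sits on the unity line."""
        n = min(len(o), len(p))
        o, p = np.array(o[:n]), np.array(p[:n])
        if np.ptp(p) < 1e-6:
            return
        reg = unity_regression(o, p)
        rss = reg.syx_rmse**2 * (n - 2)
        sspe = float(np.sum((o - p) ** 2))
        assert sspe >= rss - 1e-9
        if abs(reg.intercept) > 1e-6 or abs(reg.slope - 1) > 1e-6:
            assert sspe > rss


class TestEvaluateEquation:
    def test_perfect_predictor_flagged(self):
        config_data = generate_dataset(
            scaled_config(20, 0, noise_sd=0.0), seed=5
        ).subset("nonlactating")
        report = evaluate_equation(config_data, "DMI_2022")
        assert report.perfect_prediction
        assert report.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(report.u_bias_pct)

    def test_self_consistency_recovers_unity_line(self):
        """Data generated by the new DMI model evaluates to slope 1, intercept 0."""
        data = generate_dataset(scaled_config(500, 0), seed=11).subset("nonlactating")
        report = evaluate_equation(data, "DMI_2022")
        assert abs(report.slope - 1.0) < 0.1
        assert abs(report.intercept) < 1.0

    def test_classical_equation_underpredicts_high_intake(self):
        """Equation A on modern-style data shows the documented slope > 1."""
        data = generate_dataset(scaled_config(500, 0), seed=11).subset("nonlactating")
        report = evaluate_equation(data, "A")
        assert report.slope > 1.0
        assert report.p_slope_one < 0.05

    def test_missing_observed_dmi_rejected(self):
        ds = Dataset([CowObservation("nonlactating", 589, 1.25)])
        with pytest.raises(ValueError, match="dmi_obs"):
            evaluate_equation(ds, "A")
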