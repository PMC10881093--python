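"""Observed-vs-predicted validation of intake equations.

The validation machinery is the unity-line regression

    observed = a + b * predicted + e,

with marginal t-tests of a = 0 and b = 1 and a joint 2-df F-test, plus
two error summaries measured in kg/d:

* RMSD — root mean squared deviation of observed values about the unity
  line y = x, sqrt(sum((O - P)^2) / n).  The quantity that matters when
  prediction is the goal.
* Sy.x / RMSE — residual scatter about the *fitted* regression line,
  sqrt(RSS / (n - 2)).  RMSD >= RMSE always, with equality only when
  the fit is perfect (a = 0, b = 1).

Theil's decomposition partitions the squared sum of prediction error
SSPE = sum((O - P)^2) exactly into

    SSPE = n*(Obar - Pbar)^2        (mean bias)
         + (b - 1)^2 * Sxx          (slope deviation from unity)
         + RSS                      (random disturbance)

where Sxx = sum((P - Pbar)^2) and RSS is the residual sum of squares of
the observed-on-predicted regression; the cross terms vanish by OLS
orthogonality.  Each component is reported as a percent of SSPE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .data import Dataset
from .equations import EquationSpec, get_equation, predict_dmi

__all__ = [
    "UnityRegression",
    "TheilDecomposition",
    "EvaluationReport",
    "unity_regression",
    "rmsd",
    "theil_decomposition",
    "evaluate_equation",
    "DegenerateDesignError",
    "PerfectPredictionError",
]


class DegenerateDesignError(ValueError):
    """Predictor is constant; the unity-line regression is undefined."""


class PerfectPredictionError(ValueError):
    """SSPE is zero; the Theil decomposition is undefined."""


@dataclass(frozen=True)
class UnityRegression:
    """OLS of observed on predicted with unity-line hypothesis tests."""

    n: int
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    r2: float
    syx_rmse: float
    p_intercept_zero: float
    p_slope_one: float
    p_joint: float


@dataclass(frozen=True)
class TheilDecomposition:
    sspe: float
    u_bias_pct: float
    u_slope_pct: float
    u_error_pct: float


@dataclass(frozen=True)
class EvaluationReport:
    """Unity-line validation of one equation on one dataset."""

    equation_id: str
    n: int
    intercept: float
    se_intercept: float
    slope: float
    se_slope: float
    p_intercept_zero: float
    p_slope_one: float
    p_joint: float
    r2: float
    syx_rmse: float
    rmsd: float
    sspe: float
    u_bias_pct: float
    u_slope_pct: float
    u_error_pct: float
    perfect_prediction: bool = False


def _validate_pair(observed, predicted, min_n: int = 1):
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError(f"observed and predicted must be 1-d and equal length, got {o.shape} vs {p.shape}")
    if o.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {o.size}")
    return o, p


def unity_regression(observed, predicted) -> UnityRegression:
    """Regress observed DMI (y) on predicted DMI (x); test a=0 and b=1.

    Marginal tests are two-sided t-tests with n-2 df; ``p_joint`` is the
    2-df F-test of (a, b) = (0, 1).
    """
    o, p = _validate_pair(observed, predicted, min_n=3)
    if np.ptp(p) == 0:
        raise DegenerateDesignError("predicted values are constant")
    x = sm.add_constant(p)
    fit = sm.OLS(o, x).fit()
    a, b = fit.params
    se_a, se_b = fit.bse
    n = o.size
    df = n - 2
    rss = float(fit.ssr)
    syx = math.sqrt(rss / df)
    r2 = float(fit.rsquared)
    p_a = float(fit.pvalues[0])
    t_b = (b - 1.0) / se_b
    p_b = 2.0 * float(stats.t.sf(abs(t_b), df))
    joint = fit.f_test((np.eye(2), np.array([0.0, 1.0])))
    return UnityRegression(
        n=n,
        intercept=float(a),
        slope=float(b),
        se_intercept=float(se_a),
        se_slope=float(se_b),
        r2=r2,
        syx_rmse=syx,
        p_intercept_zero=p_a,
        p_slope_one=p_b,
        p_joint=float(joint.pvalue),
    )


def rmsd(observed, predicted, ddof: int = 0) -> float:
    """Root mean squared deviation about the unity line, kg/d.

    The divisor is n by default (a population-style average deviation);
    ``ddof`` is configurable for callers wanting a corrected version.
    """
    o, p = _validate_pair(observed, predicted, min_n=1)
    n = o.size
    if n - ddof <= 0:
        raise ValueError("ddof leaves no degrees of freedom")
    return float(np.sqrt(np.sum((o - p) ** 2) / (n - ddof)))


def theil_decomposition(observed, predicted) -> TheilDecomposition:
    """Partition SSPE into bias, slope, and random components (percents).

    Raises :class:`PerfectPredictionError` when SSPE = 0 (the
    decomposition is undefined for a perfect predictor).
    """
    o, p = _validate_pair(observed, predicted, min_n=3)
    sspe = float(np.sum((o - p) ** 2))
    if sspe == 0.0:
        raise PerfectPredictionError("observed equals predicted; SSPE is zero")
    obar, pbar = o.mean(), p.mean()
    sxx = float(np.sum((p - pbar) ** 2))
    if sxx == 0:
        raise DegenerateDesignError("predicted values are constant")
    b = float(np.sum((p - pbar) * (o - obar)) / sxx)
    bias = o.size * (obar - pbar) ** 2
    slope = (b - 1.0) ** 2 * sxx
    error = sspe - bias - slope  # equals the regression RSS by orthogonality
    return TheilDecomposition(
        sspe=sspe,
        u_bias_pct=100.0 * bias / sspe,
        u_slope_pct=100.0 * slope / sspe,
        u_error_pct=100.0 * error / sspe,
    )


def evaluate_equation(
    data: Dataset,
    eq: EquationSpec | str,
    **predict_kwargs,
) -> EvaluationReport:
    """Full unity-line validation of one equation on one dataset.

    All observations must carry ``dmi_obs`` and satisfy the equation's
    stage/milk requirements.  When the equation predicts perfectly the
    Theil components are reported as NaN and the report is flagged.
    """
    if isinstance(eq, str):
        eq = get_equation(eq)
    observed = []
    predicted = []
    for i, obs in enumerate(data):
        if obs.dmi_obs is None:
            raise ValueError(f"observation {i} lacks dmi_obs; cannot evaluate")
        observed.append(obs.dmi_obs)
        predicted.append(predict_dmi(eq, obs, **predict_kwargs).dmi_pred)
    o = np.asarray(observed)
    p = np.asarray(predicted)
    reg = unity_regression(o, p)
    deviation = rmsd(o, p)
    try:
        theil = theil_decomposition(o, p)
        perfect = False
    except PerfectPredictionError:
        theil = TheilDecomposition(0.0, math.nan, math.nan, math.nan)
        perfect = True
    return EvaluationReport(
        equation_id=eq.id,
        n=reg.n,
        intercept=reg.intercept,
        se_intercept=reg.se_intercept,
        slope=reg.slope,
        se_slope=reg.se_slope,
        p_intercept_zero=reg.p_intercept_zero,
        p_slope_one=reg.p_slope_one,
        p_joint=reg.p_joint,
        r2=reg.r2,
        syx_rmse=reg.syx_rmse,
        rmsd=deviation,
        sspe=theil.sspe,
        u_bias_pct=theil.u_bias_pct,
        u_slope_pct=theil.u_slope_pct,
        u_error_pct=theil.u_error_pct,
        perfect_prediction=perfect,
    )
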