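"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a statistic by the most literal route available
(explicit normal equations, leave-one-out refits, correlation-matrix
algebra) so the production code can be checked against something that
shares none of its implementation.
"""

from __future__ import annotations

import numpy as np


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Coefficients by explicit (X'X)^-1 X'y with a prepended intercept."""
    x = np.column_stack([np.ones(len(y)), np.asarray(x, dtype=float)])
    xtx = x.T @ x
    return np.linalg.inv(xtx) @ x.T @ np.asarray(y, dtype=float)


def externally_studentized(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out studentized residuals by literal refitting.

    For each i: fit OLS without observation i, predict y_i, and scale
    the deletion residual by its standard error under the reduced fit.
    """
    x = np.column_stack([np.ones(len(y)), np.asarray(x, dtype=float)])
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        xi, yi = x[keep], y[keep]
        beta = np.linalg.inv(xi.T @ xi) @ xi.T @ yi
        resid = yi - xi @ beta
        s2 = resid @ resid / (n - 1 - p)
        xrow = x[i]
        var = s2 * (1.0 + xrow @ np.linalg.inv(xi.T @ xi) @ xrow)
        out[i] = (y[i] - xrow @ beta) / np.sqrt(var)
    return out


def wright_path_coefficients(nem, stage, mbw, dmi):
    """Standardized path coefficients from the correlation matrix alone.

    Wright's tracing rules for the recursive system
    mbw ~ nem + stage; dmi ~ nem + stage + mbw reduce to solving the
    normal equations in correlation form: R_xx p = r_xy.
    """
    z = np.corrcoef(np.vstack([nem, stage, mbw, dmi]))
    # mbw equation: predictors (nem, stage)
    p_mbw = np.linalg.solve(z[:2, :2], z[:2, 2])
    # dmi equation: predictors (nem, stage, mbw)
    p_dmi = np.linalg.solve(z[:3, :3], z[:3, 3])
    return {
        "nem->mbw": p_mbw[0],
        "stage->mbw": p_mbw[1],
        "nem->dmi": p_dmi[0],
        "stage->dmi": p_dmi[1],
        "mbw->dmi": p_dmi[2],
    }
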