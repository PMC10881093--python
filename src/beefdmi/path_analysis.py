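"""Recursive path analysis of diet energy, stage, body weight, and intake.

The causal diagram has two exogenous variables — diet NEm and STAGE —
and two endogenous ones: metabolic body weight SBW^0.75 (heavier cows
tend to be on energy-denser diets, and lactating cows weigh less) and
DMI.  Because the model is recursive and just-identified, the
standardized path coefficients of a covariance-structure fit coincide
with standardized slopes from two sequential OLS regressions:

    SBW^0.75 ~ NEm + STAGE
    DMI      ~ NEm + STAGE + SBW^0.75

All variables are z-scored first (STAGE as its 0/1 dummy standardized
by its sample SD, the convention that matches coefficients from a
covariance-matrix fit).  Indirect effects are products of the two
constituent paths and total effects are direct + indirect, exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import Dataset

__all__ = ["PathCoefficient", "PathModel", "fit_path_model"]

SIGNIFICANCE_LEVELS = ((0.001, "***"), (0.05, "*"))


def _stars(p: float) -> str:
    for cut, mark in SIGNIFICANCE_LEVELS:
        if p < cut:
            return mark
    return ""


@dataclass(frozen=True)
class PathCoefficient:
    source: str
    target: str
    coefficient: float  # standardized
    t_value: float
    p_value: float

    @property
    def stars(self) -> str:
        return _stars(self.p_value)


@dataclass(frozen=True)
class PathModel:
    """Standardized direct, indirect, and total effects on DMI."""

    n: int
    nem_to_mbw: PathCoefficient
    stage_to_mbw: PathCoefficient
    nem_to_dmi: PathCoefficient
    stage_to_dmi: PathCoefficient
    mbw_to_dmi: PathCoefficient
    indirect_nem_to_dmi: float
    indirect_stage_to_dmi: float
    total_nem_to_dmi: float
    total_stage_to_dmi: float

    def paths(self) -> tuple[PathCoefficient, ...]:
        return (
            self.nem_to_mbw,
            self.stage_to_mbw,
            self.nem_to_dmi,
            self.stage_to_dmi,
            self.mbw_to_dmi,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": p.source,
                "target": p.target,
                "effect": "direct",
                "coefficient": p.coefficient,
                "t_value": p.t_value,
                "p_value": p.p_value,
                "significance": p.stars,
            }
            for p in self.paths()
        ]
        rows.append(
            {"source": "diet_nem", "target": "dmi", "effect": "indirect",
             "coefficient": self.indirect_nem_to_dmi, "t_value": np.nan,
             "p_value": np.nan, "significance": ""}
        )
        rows.append(
            {"source": "stage", "target": "dmi", "effect": "indirect",
             "coefficient": self.indirect_stage_to_dmi, "t_value": np.nan,
             "p_value": np.nan, "significance": ""}
        )
        rows.append(
            {"source": "diet_nem", "target": "dmi", "effect": "total",
             "coefficient": self.total_nem_to_dmi, "t_value": np.nan,
             "p_value": np.nan, "significance": ""}
        )
        rows.append(
            {"source": "stage", "target": "dmi", "effect": "total",
             "coefficient": self.total_stage_to_dmi, "t_value": np.nan,
             "p_value": np.nan, "significance": ""}
        )
        return pd.DataFrame(rows)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant variable cannot be standardized")
    return (x - x.mean()) / sd


def _std_ols(y: np.ndarray, xcols: dict[str, np.ndarray]):
    x = sm.add_constant(np.column_stack(list(xcols.values())))
    fit = sm.OLS(y, x).fit()
    names = list(xcols)
    coefs = dict(zip(names, fit.params[1:]))
    tvals = dict(zip(names, fit.tvalues[1:]))
    pvals = dict(zip(names, fit.pvalues[1:]))
    return coefs, tvals, pvals


def fit_path_model(data: Dataset) -> PathModel:
    """Fit the recursive path model and derive indirect/total effects.

    Requires observed DMI on every observation, both production stages,
    and n >= 10.
    """
    frame = data.to_frame()
    n = len(frame)
    if n < 10:
        raise ValueError(f"path analysis requires n >= 10, got {n}")
    if frame["dmi_obs"].isna().any():
        raise ValueError("all observations must carry dmi_obs")
    if frame["stage_code"].nunique() < 2:
        raise ValueError("both production stages must be represented")
    nem = _zscore(frame["diet_nem"].to_numpy(dtype=float))
    stage = _zscore(frame["stage_code"].to_numpy(dtype=float))
    mbw = _zscore(frame["mbw"].to_numpy(dtype=float))
    dmi = _zscore(frame["dmi_obs"].to_numpy(dtype=float))

    if abs(np.corrcoef(nem, stage)[0, 1]) > 1 - 1e-10:
        raise np.linalg.LinAlgError("exogenous predictors are collinear")

    c1, t1, p1 = _std_ols(mbw, {"nem": nem, "stage": stage})
    c2, t2, p2 = _std_ols(dmi, {"nem": nem, "stage": stage, "mbw": mbw})

    nem_mbw = PathCoefficient("diet_nem", "mbw", float(c1["nem"]), float(t1["nem"]), float(p1["nem"]))
    stage_mbw = PathCoefficient("stage", "mbw", float(c1["stage"]), float(t1["stage"]), float(p1["stage"]))
    nem_dmi = PathCoefficient("diet_nem", "dmi", float(c2["nem"]), float(t2["nem"]), float(p2["nem"]))
    stage_dmi = PathCoefficient("stage", "dmi", float(c2["stage"]), float(t2["stage"]), float(p2["stage"]))
    mbw_dmi = PathCoefficient("mbw", "dmi", float(c2["mbw"]), float(t2["mbw"]), float(p2["mbw"]))

    ind_nem = nem_mbw.coefficient * mbw_dmi.coefficient
    ind_stage = stage_mbw.coefficient * mbw_dmi.coefficient
    return PathModel(
        n=n,
        nem_to_mbw=nem_mbw,
        stage_to_mbw=stage_mbw,
        nem_to_dmi=nem_dmi,
        stage_to_dmi=stage_dmi,
        mbw_to_dmi=mbw_dmi,
        indirect_nem_to_dmi=ind_nem,
        indirect_stage_to_dmi=ind_stage,
        total_nem_to_dmi=nem_dmi.coefficient + ind_nem,
        total_stage_to_dmi=stage_dmi.coefficient + ind_stage,
    )
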