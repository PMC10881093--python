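"""Refitting the two new intake models and lactation summaries.

Two model families are fit by ordinary least squares on treatment means
(unweighted by default — an optional weight vector is accepted):

* NEMI model — response is daily net-energy intake per unit metabolic
  weight, NEMI = DMI * NEm / SBW^0.75 (Mcal/kg^0.75/d); candidate terms
  are diet NEm, NEm^2, the STAGE dummy, and NEm x STAGE.
* DMI model — response is DMI (kg/d) directly; candidates are SBW^0.75,
  NEm, NEm^2, STAGE, NEm x STAGE, and SBW^0.75 x STAGE.

Term selection is deterministic backward elimination: interaction terms
are dropped first (highest p-value first, while p > alpha), then the
quadratic; main effects are never dropped.  A surviving quadratic is
additionally checked against an overparameterization rule — if the
implied predicted-DMI curve over the observed NEm range is not monotone
non-decreasing (a concave-up/concave-down artifact with intake rising at
both extremes), the quadratic model is flagged and the linear model
reported instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import Dataset, CowObservation

__all__ = [
    "FittedModel",
    "MilkResponseSummary",
    "LactationEnergyBudget",
    "fit_nemi_model",
    "fit_dmi_model",
    "dmi_from_nemi",
    "milk_response_summary",
    "lactation_energy_budget",
    "StageInestimableError",
]

NEMI = "NEMI"
DMI = "DMI"

_ALPHA = 0.05


class StageInestimableError(ValueError):
    """Only one production stage present; the STAGE term is inestimable."""


@dataclass
class FittedModel:
    """An OLS fit of the NEMI or DMI model after term selection."""

    response: str  # "NEMI" or "DMI"
    terms: list[str]
    coefficients: dict[str, float]
    ses: dict[str, float]
    p_values: dict[str, float]
    adj_r2: float
    syx: float
    n: int
    dropped: list[str] = field(default_factory=list)
    quadratic_flagged: bool = False

    def design_row(self, obs: CowObservation) -> dict[str, float]:
        feats = {
            "intercept": 1.0,
            "nem": obs.diet_nem,
            "nem2": obs.diet_nem**2,
            "stage": float(obs.stage_code),
            "mbw": obs.mbw,
        }
        feats["nem:stage"] = feats["nem"] * feats["stage"]
        feats["mbw:stage"] = feats["mbw"] * feats["stage"]
        return {t: feats[t] for t in self.terms}

    def predict(self, obs: CowObservation) -> float:
        """Predicted response (NEMI in Mcal/kg^0.75/d, or DMI in kg/d)."""
        row = self.design_row(obs)
        return float(sum(self.coefficients[t] * v for t, v in row.items()))

    def predict_dmi(self, obs: CowObservation) -> float:
        """Predicted DMI, converting through NEm for a NEMI-response fit."""
        if self.response == DMI:
            return self.predict(obs)
        return dmi_from_nemi(self, obs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coefficient": [self.coefficients[t] for t in self.terms],
                "se": [self.ses[t] for t in self.terms],
                "p_value": [self.p_values[t] for t in self.terms],
            }
        )


@dataclass(frozen=True)
class MilkResponseSummary:
    """Feed-intake response to lactation expressed per kg of milk yield."""

    stage_coefficient: float  # kg/d intake adjustment for lactation
    mean_milk: float  # kg/d
    intake_per_kg_milk: float  # kg DMI per kg milk (exact ratio)
    comparison_nasem: float  # kg/d, the 0.2 kg-per-kg convention

    @property
    def intake_per_kg_milk_2dp(self) -> float:
        return round(self.intake_per_kg_milk, 2)


@dataclass(frozen=True)
class LactationEnergyBudget:
    """Energy demand of lactation vs the energy the intake response supplies."""

    lactation_requirement: float  # Mcal NEm/d
    intake_response: float  # Mcal NEm/d
    balance: float  # Mcal NEm/d (response - requirement)


def _design(frame: pd.DataFrame, terms: list[str]) -> np.ndarray:
    cols = {
        "intercept": np.ones(len(frame)),
        "nem": frame["diet_nem"].to_numpy(dtype=float),
        "nem2": frame["diet_nem"].to_numpy(dtype=float) ** 2,
        "stage": frame["stage_code"].to_numpy(dtype=float),
        "mbw": frame["mbw"].to_numpy(dtype=float),
    }
    cols["nem:stage"] = cols["nem"] * cols["stage"]
    cols["mbw:stage"] = cols["mbw"] * cols["stage"]
    return np.column_stack([cols[t] for t in terms])


def _ols(frame: pd.DataFrame, y: np.ndarray, terms: list[str], weights=None):
    x = _design(frame, terms)
    if weights is None:
        fit = sm.OLS(y, x).fit()
    else:
        fit = sm.WLS(y, x, weights=np.asarray(weights, dtype=float)).fit()
    return fit


def _select_terms(
    frame: pd.DataFrame,
    y: np.ndarray,
    mains: list[str],
    interactions: list[str],
    quadratic: str | None,
    weights,
    alpha: float,
):
    """Backward elimination: interactions first (highest p first), then quadratic."""
    terms = ["intercept", *mains]
    if quadratic:
        terms.append(quadratic)
    terms.extend(interactions)
    dropped: list[str] = []
    fit = _ols(frame, y, terms, weights)
    while True:
        pvals = dict(zip(terms, fit.pvalues))
        droppable = [t for t in interactions if t in terms and pvals[t] > alpha]
        if not droppable and quadratic in terms and pvals[quadratic] > alpha:
            droppable = [quadratic]
        if not droppable:
            break
        worst = max(droppable, key=lambda t: pvals[t])
        terms.remove(worst)
        dropped.append(worst)
        fit = _ols(frame, y, terms, weights)
    return terms, dropped, fit


def _monotone_dmi_curve(model: "FittedModel", frame: pd.DataFrame) -> bool:
    """Check predicted DMI is non-decreasing in NEm over the observed range."""
    nem_lo, nem_hi = frame["diet_nem"].min(), frame["diet_nem"].max()
    grid = np.linspace(nem_lo, nem_hi, 101)
    sbw = float(frame["sbw_kg"].median())
    for stage in ("nonlactating", "lactating"):
        preds = [
            model.predict_dmi(
                CowObservation(stage=stage, sbw_kg=sbw, diet_nem=float(g))
            )
            for g in grid
        ]
        if np.any(np.diff(preds) < -1e-10):
            return False
    return True


def _package_fit(response, fit, terms, dropped, n) -> FittedModel:
    params = dict(zip(terms, np.asarray(fit.params, dtype=float)))
    ses = dict(zip(terms, np.asarray(fit.bse, dtype=float)))
    pvals = dict(zip(terms, np.asarray(fit.pvalues, dtype=float)))
    return FittedModel(
        response=response,
        terms=list(terms),
        coefficients=params,
        ses=ses,
        p_values=pvals,
        adj_r2=float(fit.rsquared_adj),
        syx=float(np.sqrt(fit.ssr / fit.df_resid)),
        n=n,
        dropped=list(dropped),
    )


def _prepare(data: Dataset) -> tuple[pd.DataFrame, np.ndarray]:
    frame = data.to_frame()
    if frame.empty:
        raise ValueError("empty dataset")
    if frame["dmi_obs"].isna().any():
        raise ValueError("all observations must carry dmi_obs for fitting")
    if frame["stage_code"].nunique() < 2:
        raise StageInestimableError("both production stages must be represented")
    return frame, frame["dmi_obs"].to_numpy(dtype=float)


def fit_nemi_model(data: Dataset, alpha: float = _ALPHA, weights=None) -> FittedModel:
    """Fit the scaled energy-intake (NEMI) model.

    The response is (DMI * NEm) / SBW^0.75 per observation.  Candidates:
    NEm, NEm^2, STAGE, NEm x STAGE.  The interaction and quadratic are
    dropped when non-significant; a surviving quadratic whose implied
    DMI curve is non-monotone over the data's NEm range is flagged as
    overparameterized and the linear model is reported.
    """
    frame, dmi = _prepare(data)
    nemi = dmi * frame["diet_nem"].to_numpy(dtype=float) / frame["mbw"].to_numpy(dtype=float)
    terms, dropped, fit = _select_terms(
        frame, nemi, mains=["nem", "stage"], interactions=["nem:stage"],
        quadratic="nem2", weights=weights, alpha=alpha,
    )
    model = _package_fit(NEMI, fit, terms, dropped, len(frame))
    if "nem2" in terms and not _monotone_dmi_curve(model, frame):
        terms = [t for t in terms if t != "nem2"]
        dropped = dropped + ["nem2"]
        fit = _ols(frame, nemi, terms, weights)
        model = _package_fit(NEMI, fit, terms, dropped, len(frame))
        model.quadratic_flagged = True
    return model


def fit_dmi_model(data: Dataset, alpha: float = _ALPHA, weights=None) -> FittedModel:
    """Fit the direct DMI model.

    Candidates: SBW^0.75, NEm, NEm^2, STAGE, NEm x STAGE, SBW^0.75 x
    STAGE.  Non-significant interactions are dropped first (highest p
    first), then the quadratic; the three main effects stay.
    """
    frame, dmi = _prepare(data)
    terms, dropped, fit = _select_terms(
        frame, dmi, mains=["stage", "nem", "mbw"],
        interactions=["nem:stage", "mbw:stage"],
        quadratic="nem2", weights=weights, alpha=alpha,
    )
    model = _package_fit(DMI, fit, terms, dropped, len(frame))
    if "nem2" in terms and not _monotone_dmi_curve(model, frame):
        terms = [t for t in terms if t != "nem2"]
        dropped = dropped + ["nem2"]
        fit = _ols(frame, dmi, terms, weights)
        model = _package_fit(DMI, fit, terms, dropped, len(frame))
        model.quadratic_flagged = True
    return model


def dmi_from_nemi(model: FittedModel, obs: CowObservation) -> float:
    """Convert a NEMI-model prediction to daily feed intake, kg/d.

    DMI = predicted NEMI * SBW^0.75 / NEm.
    """
    if model.response != NEMI:
        raise ValueError(f"model response is {model.response}, expected {NEMI}")
    return model.predict(obs) * obs.mbw / obs.diet_nem


def milk_response_summary(stage_coefficient: float, mean_milk: float) -> MilkResponseSummary:
    """Intake response to lactation per kg of milk yield.

    Divides the fitted lactation intercept adjustment (kg/d) by mean
    milk yield, and reports the conventional 0.2 kg-per-kg adjustment
    (0.2 * mean milk) for comparison.
    """
    if not mean_milk > 0:
        raise ValueError(f"mean_milk must be positive, got {mean_milk}")
    return MilkResponseSummary(
        stage_coefficient=stage_coefficient,
        mean_milk=mean_milk,
        intake_per_kg_milk=stage_coefficient / mean_milk,
        comparison_nasem=0.2 * mean_milk,
    )


def lactation_energy_budget(
    milk_kg_d: float,
    diet_nem: float,
    stage_coefficient: float,
    milk_energy: float = 0.72,
    maintenance_increment: float = 2.2,
) -> LactationEnergyBudget:
    """Energy demand of lactation vs energy supplied by the intake response.

    Requirement = milk yield * milk energy density + the maintenance
    increment of lactation (Mcal NEm/d); the intake response converts
    the lactation intake adjustment to energy via diet NEm.  A negative
    balance means the intake response alone does not cover lactation's
    energy demand at that diet energy density.
    """
    for name, val in (
        ("milk_kg_d", milk_kg_d),
        ("diet_nem", diet_nem),
        ("stage_coefficient", stage_coefficient),
        ("milk_energy", milk_energy),
    ):
        if val < 0:
            raise ValueError(f"{name} must be non-negative, got {val}")
    if maintenance_increment < 0:
        raise ValueError("maintenance_increment must be non-negative")
    requirement = milk_kg_d * milk_energy + maintenance_increment
    response = stage_coefficient * diet_nem
    return LactationEnergyBudget(
        lactation_requirement=requirement,
        intake_response=response,
        balance=response - requirement,
    )
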