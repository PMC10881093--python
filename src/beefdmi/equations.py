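"""Closed-form prediction of daily dry matter intake (DMI) in beef cows.

Eight equations are implemented.  Six are previously published:

* A (nonlactating) / D (lactating): DMI scales with metabolic weight and
  linearly with diet NEm; D adds 0.2 kg per kg milk yield.
* B (nonlactating) / E (lactating): net-energy intake per unit metabolic
  weight is quadratic in NEm and converted to feed by dividing by NEm.
* C (nonlactating) / F (lactating): intake as a concave quadratic in NEm
  scaled by full shrunk body weight (not metabolic weight), so intake
  stabilizes at about 1.4-1.5 Mcal/kg.

Two are the new models fitted on the pooled validation dataset:

* NEMI_2022: daily NEm intake per kg SBW^0.75,
  NEMI = 0.224*NEm + 0.0346*STAGE - 0.142 (Mcal/kg^0.75/d), converted to
  DMI by NEMI * SBW^0.75 / NEm.
* DMI_2022: DMI = 3.27*STAGE + 9.21*NEm + 0.133*SBW^0.75 - 14.38.

The NEMI response is documented in its source on a kcal scale, but the
printed coefficients are dimensionally consistent only on a Mcal scale
(0.224*1.3 - 0.142 is about 0.15 Mcal/kg^0.75); Mcal is used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import LACTATING, NONLACTATING, CowObservation, Dataset, metabolic_weight

__all__ = [
    "EquationSpec",
    "PredictionResult",
    "EQUATIONS",
    "EQUATION_IDS",
    "DEFAULT_NEM_WINDOW",
    "get_equation",
    "predict_dmi",
    "predict_dataset",
    "response_curve",
    "NemRangeWarning",
]

BOTH = "both"

#: NEm validity window (Mcal/kg DM); predictions outside it warn but run,
#: since the response curves are routinely extrapolated past the data.
DEFAULT_NEM_WINDOW = (0.7, 2.1)


class NemRangeWarning(UserWarning):
    """Diet NEm outside the equation validity window; extrapolating."""


class ApplicabilityError(ValueError):
    """Observation's production stage does not match the equation."""


class MissingFieldError(ValueError):
    """A field the equation requires (milk yield) is absent."""


@dataclass(frozen=True)
class EquationSpec:
    """Identifier plus coefficient set for one prediction formula."""

    id: str
    applicable_stage: str  # nonlactating | lactating | both
    requires_milk: bool
    coefficients: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", MappingProxyType(dict(self.coefficients)))


@dataclass(frozen=True)
class PredictionResult:
    equation_id: str
    dmi_pred: float
    nemi_pred: float | None = None  # Mcal/kg^0.75/d, NEMI_2022 only


EQUATIONS: dict[str, EquationSpec] = {
    "A": EquationSpec("A", NONLACTATING, False, {"a": 0.0194, "b": 0.0545}),
    "B": EquationSpec("B", NONLACTATING, False, {"a": 0.04997, "b": 0.04631}),
    "C": EquationSpec("C", NONLACTATING, False, {"a": -0.0323, "b": 0.0944, "c": -0.0418}),
    "D": EquationSpec("D", LACTATING, True, {"a": 0.0194, "b": 0.0545, "milk": 0.2}),
    "E": EquationSpec("E", LACTATING, True, {"a": 0.04997, "b": 0.04631, "milk": 0.2}),
    "F": EquationSpec("F", LACTATING, False, {"a": -0.0261, "b": 0.07777, "c": -0.0277}),
    "NEMI_2022": EquationSpec(
        "NEMI_2022", BOTH, False, {"nem": 0.224, "stage": 0.0346, "intercept": -0.142}
    ),
    "DMI_2022": EquationSpec(
        "DMI_2022", BOTH, False, {"stage": 3.27, "nem": 9.21, "mbw": 0.133, "intercept": -14.38}
    ),
}

EQUATION_IDS = tuple(EQUATIONS)


def get_equation(equation_id: str) -> EquationSpec:
    try:
        return EQUATIONS[equation_id]
    except KeyError:
        raise KeyError(
            f"unknown equation {equation_id!r}; choose from {', '.join(EQUATION_IDS)}"
        ) from None


def predict_dmi(
    eq: EquationSpec | str,
    obs: CowObservation,
    nem_window: tuple[float, float] = DEFAULT_NEM_WINDOW,
) -> PredictionResult:
    """Predict daily DMI (kg/d) for one treatment mean.

    Raises :class:`ApplicabilityError` on a stage mismatch and
    :class:`MissingFieldError` when milk yield is required but absent.
    NEm outside ``nem_window`` emits :class:`NemRangeWarning`.
    """
    if isinstance(eq, str):
        eq = get_equation(eq)
    if eq.applicable_stage != BOTH and obs.stage != eq.applicable_stage:
        raise ApplicabilityError(
            f"equation {eq.id} applies to {eq.applicable_stage} cows, got {obs.stage}"
        )
    milk = obs.milk_kg_d
    if eq.requires_milk and milk is None:
        raise MissingFieldError(f"equation {eq.id} requires milk_kg_d")
    nem = obs.diet_nem
    lo, hi = nem_window
    if not lo <= nem <= hi:
        warnings.warn(
            f"diet NEm {nem} Mcal/kg outside validity window [{lo}, {hi}] for equation {eq.id}",
            NemRangeWarning,
            stacklevel=2,
        )
    c = eq.coefficients
    mbw = obs.mbw
    sbw = obs.sbw_kg
    nemi: float | None = None
    if eq.id == "A":
        dmi = mbw * (c["a"] + c["b"] * nem)
    elif eq.id == "B":
        dmi = mbw * (c["a"] * nem**2 + c["b"]) / nem
    elif eq.id in ("C", "F"):
        dmi = (c["a"] * nem**2 + c["b"] * nem + c["c"]) * sbw
    elif eq.id == "D":
        dmi = mbw * (c["a"] + c["b"] * nem) + c["milk"] * milk
    elif eq.id == "E":
        dmi = (mbw * (c["a"] * nem**2 + c["b"]) + c["milk"] * milk) / nem
    elif eq.id == "NEMI_2022":
        nemi = c["nem"] * nem + c["stage"] * obs.stage_code + c["intercept"]
        dmi = nemi * mbw / nem
    elif eq.id == "DMI_2022":
        dmi = c["stage"] * obs.stage_code + c["nem"] * nem + c["mbw"] * mbw + c["intercept"]
    else:  # pragma: no cover - registry is closed
        raise KeyError(eq.id)
    return PredictionResult(eq.id, float(dmi), nemi if nemi is None else float(nemi))


def predict_dataset(
    eq: EquationSpec | str,
    data: Dataset,
    nem_window: tuple[float, float] = DEFAULT_NEM_WINDOW,
) -> pd.DataFrame:
    """Predict DMI for every observation; one row per treatment mean."""
    if isinstance(eq, str):
        eq = get_equation(eq)
    rows = []
    for obs in data:
        result = predict_dmi(eq, obs, nem_window=nem_window)
        rows.append(
            {
                "stage": obs.stage,
                "sbw_kg": obs.sbw_kg,
                "diet_nem": obs.diet_nem,
                "milk_kg_d": obs.milk_kg_d,
                "dmi_obs": obs.dmi_obs,
                "equation_id": eq.id,
                "dmi_pred": result.dmi_pred,
                "nemi_pred": result.nemi_pred,
            }
        )
    return pd.DataFrame(rows)


def response_curve(
    eq: EquationSpec | str,
    sbw_kg: float,
    nem_grid: Sequence[float],
    milk_kg_d: float | None = None,
    stage: str | None = None,
    nem_window: tuple[float, float] = DEFAULT_NEM_WINDOW,
) -> pd.DataFrame:
    """Predicted DMI across a grid of diet NEm values for a reference cow.

    Regenerates the published response-curve families (545-kg cow;
    lactating case at 7 kg milk/d).  ``stage`` defaults to the
    equation's applicable stage, else lactating when milk is given.
    """
    if isinstance(eq, str):
        eq = get_equation(eq)
    grid = np.asarray(list(nem_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("nem_grid must be non-empty")
    if np.any(grid <= 0):
        raise ValueError("nem_grid values must be positive")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("nem_grid must be strictly increasing")
    if stage is None:
        if eq.applicable_stage != BOTH:
            stage = eq.applicable_stage
        else:
            stage = LACTATING if milk_kg_d is not None else NONLACTATING
    milk = milk_kg_d if stage == LACTATING else None
    rows = []
    for nem in grid:
        obs = CowObservation(stage=stage, sbw_kg=sbw_kg, diet_nem=float(nem), milk_kg_d=milk)
        result = predict_dmi(eq, obs, nem_window=nem_window)
        rows.append({"diet_nem": float(nem), "dmi_pred": result.dmi_pred, "nemi_pred": result.nemi_pred})
    out = pd.DataFrame(rows)
    out.insert(0, "equation_id", eq.id)
    return out
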