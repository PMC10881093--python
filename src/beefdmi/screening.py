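"""Outlier screening of treatment means by studentized residuals.

Observed DMI is regressed on diet NEm, metabolic weight SBW^0.75, and
production stage (main effects only), and observations whose externally
studentized (leave-one-out) residual exceeds a threshold in absolute
value — 3 by default — are flagged.  Screening is a single pass; the
flagged set is reported, not iteratively re-screened.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .data import Dataset

__all__ = ["OutlierReport", "flag_outliers", "SampleSizeError"]

_MODEL_TERMS = ("diet_nem", "mbw", "stage_code")


class SampleSizeError(ValueError):
    """Too few observations for the screening regression."""


@dataclass
class OutlierReport:
    """Per-observation studentized residuals and outlier flags."""

    threshold: float
    studentization: str
    table: pd.DataFrame = field(repr=False)

    @property
    def residuals(self) -> np.ndarray:
        return self.table["studentized_residual"].to_numpy()

    @property
    def flags(self) -> np.ndarray:
        return self.table["outlier"].to_numpy()

    @property
    def n_flagged(self) -> int:
        return int(self.table["outlier"].sum())

    def flagged_indices(self) -> list[int]:
        return self.table.index[self.table["outlier"]].tolist()


def _studentized(frame: pd.DataFrame, studentization: str) -> np.ndarray:
    y = frame["dmi_obs"].to_numpy(dtype=float)
    x = sm.add_constant(frame[list(_MODEL_TERMS)].to_numpy(dtype=float))
    n, p = x.shape
    if n < p + 2:
        raise SampleSizeError(f"need at least {p + 2} observations, got {n}")
    influence = OLSInfluence(sm.OLS(y, x).fit())
    if studentization == "external":
        return np.asarray(influence.resid_studentized_external)
    if studentization == "internal":
        return np.asarray(influence.resid_studentized_internal)
    raise ValueError(f"studentization must be 'external' or 'internal', got {studentization!r}")


def flag_outliers(
    data: Dataset,
    threshold: float = 3.0,
    studentization: str = "external",
    per_stage: bool = False,
) -> OutlierReport:
    """Flag treatment means with |studentized residual| > ``threshold``.

    The default studentization is external (each residual scaled by a
    variance estimate that excludes the observation itself, the SAS
    RSTUDENT convention).  ``per_stage=True`` screens the two production
    stages with separate regressions (the pooled model then drops the
    stage dummy within each subset).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    frame = data.to_frame()
    if frame.empty:
        raise SampleSizeError("empty dataset")
    if frame["dmi_obs"].isna().any():
        missing = frame.index[frame["dmi_obs"].isna()].tolist()
        raise ValueError(f"observations without dmi_obs cannot be screened: rows {missing}")
    if per_stage:
        resid = np.empty(len(frame))
        for stage, block in frame.groupby("stage", sort=False):
            y = block["dmi_obs"].to_numpy(dtype=float)
            # stage dummy is constant within stage; absorbed by the intercept
            x = sm.add_constant(block[["diet_nem", "mbw"]].to_numpy(dtype=float))
            if len(block) < x.shape[1] + 2:
                raise SampleSizeError(f"stage {stage!r}: too few observations to screen")
            influence = OLSInfluence(sm.OLS(y, x).fit())
            vals = (
                influence.resid_studentized_external
                if studentization == "external"
                else influence.resid_studentized_internal
            )
            resid[frame.index.get_indexer(block.index)] = np.asarray(vals)
    else:
        resid = _studentized(frame, studentization)
    table = pd.DataFrame(
        {
            "stage": frame["stage"],
            "sbw_kg": frame["sbw_kg"],
            "diet_nem": frame["diet_nem"],
            "dmi_obs": frame["dmi_obs"],
            "studentized_residual": resid,
            "outlier": np.abs(resid) > threshold,
        }
    )
    return OutlierReport(threshold=threshold, studentization=studentization, table=table)
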