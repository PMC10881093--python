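"""Domain types, unit conventions, and CSV I/O.

Units are fixed throughout the package: body weight in kg, intake in kg
dry matter per day, diet energy density in Mcal net energy for
maintenance (NEm) per kg dry matter, milk yield in kg/d.  The
observational unit is the *treatment mean* — the per-diet, per-group
average from a feeding trial — not the individual animal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "NONLACTATING",
    "LACTATING",
    "SHRINK_FACTOR",
    "CowObservation",
    "Dataset",
    "SchemaError",
    "RowError",
    "shrink_weight",
    "metabolic_weight",
    "read_dataset",
    "write_table",
]

logger = logging.getLogger(__name__)

NONLACTATING = "nonlactating"
LACTATING = "lactating"
STAGES = (NONLACTATING, LACTATING)

#: Live weight to shrunk body weight conversion (4% gut-fill shrink).
SHRINK_FACTOR = 0.96


class SchemaError(ValueError):
    """A required column is missing or the file layout is unusable."""


class RowError(ValueError):
    """One or more rows violate observation invariants; message is row-indexed."""


def shrink_weight(bw_kg: float) -> float:
    """Convert live body weight (kg) to shrunk body weight (kg).

    SBW = 0.96 * BW, the standard shrink applied when a study reports
    full live weight rather than shrunk weight.
    """
    if not bw_kg > 0:
        raise ValueError(f"live body weight must be positive, got {bw_kg}")
    return bw_kg * SHRINK_FACTOR


def metabolic_weight(sbw_kg: float) -> float:
    """Metabolic body weight, SBW^0.75 (kg^0.75)."""
    if not sbw_kg > 0:
        raise ValueError(f"shrunk body weight must be positive, got {sbw_kg}")
    return sbw_kg**0.75


@dataclass(frozen=True)
class CowObservation:
    """One treatment mean: a group of cows on one diet in one trial.

    Parameters
    ----------
    stage
        Production stage, ``"nonlactating"`` (gestating or open) or
        ``"lactating"``.  Coded 0/1 at computation time via
        :attr:`stage_code`.
    sbw_kg
        Study-average shrunk body weight, kg.
    diet_nem
        Diet net energy for maintenance concentration, Mcal/kg DM.
    dmi_obs
        Observed dry matter intake, kg/d (optional; required for
        evaluation and fitting).
    milk_kg_d
        Daily milk yield, kg/d (lactating cows only).
    bcs
        Body condition score on the 1-9 scale (optional, carried as data
        only — never a model predictor).
    source_id
        Free-text provenance label.
    """

    stage: str
    sbw_kg: float
    diet_nem: float
    dmi_obs: float | None = None
    milk_kg_d: float | None = None
    bcs: float | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if not self.sbw_kg > 0:
            raise ValueError(f"sbw_kg must be positive, got {self.sbw_kg}")
        if not self.diet_nem > 0:
            raise ValueError(f"diet_nem must be positive, got {self.diet_nem}")
        if self.dmi_obs is not None and not self.dmi_obs > 0:
            raise ValueError(f"dmi_obs must be positive when present, got {self.dmi_obs}")
        if self.milk_kg_d is not None:
            if self.milk_kg_d < 0:
                raise ValueError(f"milk_kg_d must be >= 0, got {self.milk_kg_d}")
            if self.stage == NONLACTATING and self.milk_kg_d != 0:
                raise ValueError("nonlactating observation cannot carry nonzero milk yield")
        if self.bcs is not None and not 1 <= self.bcs <= 9:
            raise ValueError(f"bcs must lie in [1, 9], got {self.bcs}")

    @property
    def stage_code(self) -> int:
        """0 for nonlactating, 1 for lactating (the STAGE dummy)."""
        return 0 if self.stage == NONLACTATING else 1

    @property
    def mbw(self) -> float:
        """Metabolic body weight SBW^0.75, kg^0.75."""
        return metabolic_weight(self.sbw_kg)


@dataclass
class Dataset:
    """An ordered collection of treatment means."""

    observations: list[CowObservation] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self) -> Iterator[CowObservation]:
        return iter(self.observations)

    def __getitem__(self, i: int) -> CowObservation:
        return self.observations[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self.observations == other.observations

    def stage_counts(self) -> dict[str, int]:
        counts = {NONLACTATING: 0, LACTATING: 0}
        for obs in self.observations:
            counts[obs.stage] += 1
        return counts

    def subset(self, stage: str) -> "Dataset":
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        return Dataset(
            [o for o in self.observations if o.stage == stage],
            label=f"{self.label}[{stage}]" if self.label else stage,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with derived columns ``stage_code`` and ``mbw``."""
        rows = []
        for obs in self.observations:
            rows.append(
                {
                    "stage": obs.stage,
                    "sbw_kg": obs.sbw_kg,
                    "diet_nem": obs.diet_nem,
                    "dmi_obs": obs.dmi_obs,
                    "milk_kg_d": obs.milk_kg_d,
                    "bcs": obs.bcs,
                    "source_id": obs.source_id,
                    "stage_code": obs.stage_code,
                    "mbw": obs.mbw,
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label: str = "") -> "Dataset":
        obs_fields = {f.name for f in fields(CowObservation)}
        observations = []
        errors = []
        for idx, row in frame.iterrows():
            kwargs = {}
            for name in obs_fields:
                if name in frame.columns:
                    value = row[name]
                    if pd.isna(value):
                        value = None
                    kwargs[name] = value
            try:
                observations.append(CowObservation(**kwargs))
            except (ValueError, TypeError) as exc:
                errors.append(f"row {idx}: {exc}")
        if errors:
            raise RowError("; ".join(errors))
        return cls(observations, label=label)


_REQUIRED_COLUMNS = ("stage", "diet_nem")


def read_dataset(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    label: str | None = None,
) -> Dataset:
    """Read a treatment-mean dataset from CSV.

    Required columns: ``stage``, ``diet_nem``, and either ``sbw_kg``
    (shrunk weight) or ``bw_kg`` (live weight, converted via
    :func:`shrink_weight`).  Optional columns: ``dmi_obs``,
    ``milk_kg_d``, ``bcs``, ``source_id``.  Empty cells denote absent
    optional fields; rows violating invariants are rejected with
    row-indexed messages.

    Parameters
    ----------
    column_map
        Optional mapping from file column names to canonical names,
        e.g. ``{"NEm": "diet_nem"}``.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if "sbw_kg" not in frame.columns and "bw_kg" not in frame.columns:
        missing.append("sbw_kg (or bw_kg)")
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    if "sbw_kg" not in frame.columns:
        frame["sbw_kg"] = [shrink_weight(v) for v in frame["bw_kg"]]
        logger.info("%s: converted live BW to SBW (x %.2f)", path.name, SHRINK_FACTOR)
    numeric_cols = [c for c in ("sbw_kg", "diet_nem", "dmi_obs", "milk_kg_d", "bcs") if c in frame.columns]
    errors = []
    for col in numeric_cols:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        for idx in bad:
            errors.append(f"row {idx}: unparseable numeric in column {col!r}: {frame.at[idx, col]!r}")
        frame[col] = coerced
    if errors:
        raise RowError("; ".join(errors))
    return Dataset.from_frame(frame, label=label if label is not None else path.stem)


def write_table(records, path: str | Path) -> Path:
    """Write any tabular report to CSV with a header row.

    Accepts a :class:`Dataset`, a :class:`pandas.DataFrame`, a single
    dataclass instance, or a sequence of dataclasses/mappings.  Floats
    are serialized at full (round-trip) precision, so a read-back
    recovers values bit-equal.
    """
    frame = _as_frame(records)
    if frame.empty:
        raise ValueError("refusing to write an empty table")
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def _as_frame(records) -> pd.DataFrame:
    from dataclasses import asdict, is_dataclass

    if isinstance(records, Dataset):
        frame = records.to_frame()
        return frame.drop(columns=["stage_code", "mbw"])
    if isinstance(records, pd.DataFrame):
        return records
    if is_dataclass(records) and not isinstance(records, type):
        return pd.DataFrame([asdict(records)])
    records = list(records)
    if records and is_dataclass(records[0]):
        return pd.DataFrame([asdict(r) for r in records])
    return pd.DataFrame(records)
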