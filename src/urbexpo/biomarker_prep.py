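"""Censoring rules, detection filter, standardization and descriptives for
blood biomarker panels measured with a limit of detection (LOD) and a limit
of quantification (LOQ).

Conventions: values below the LOD are substituted by ``LOD / sqrt(2)``;
values between LOD and LOQ are retained as reported by the instrument; an
analyte enters analysis only if at least a configurable fraction (default
95%) of participants are at or above its LOQ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnalyteSpec",
    "CensorStatus",
    "censor_status",
    "impute_below_lod",
    "detection_filter",
    "standardize",
    "summarize",
    "DEFAULT_PANEL",
]

BELOW_LOD = "below_lod"
BETWEEN_LOD_LOQ = "between_lod_loq"
QUANTIFIED = "quantified"

CensorStatus = str


@dataclass(frozen=True)
class AnalyteSpec:
    """LOD/LOQ metadata for one analyte (concentrations in ng/mL)."""

    name: str
    lod: float
    loq: float

    def __post_init__(self):
        if self.lod <= 0:
            raise ValueError(f"{self.name}: LOD must be > 0, got {self.lod}")
        if self.loq < self.lod:
            raise ValueError(
                f"{self.name}: LOQ {self.loq} < LOD {self.lod}")


#: PFAS congener panel with instrument limits (ng/mL) as published for the
#: assay this package emulates.
DEFAULT_PANEL: tuple[AnalyteSpec, ...] = (
    AnalyteSpec("PFBS", 0.078, 5.0),
    AnalyteSpec("PFBA", 0.41, 0.5),
    AnalyteSpec("PFNA", 0.016, 0.1),
    AnalyteSpec("PFOA", 0.009, 0.1),
    AnalyteSpec("PFOS", 0.027, 0.182),
    AnalyteSpec("PFHxS", 0.024, 0.1),
    AnalyteSpec("PFUnDA", 0.011, 0.1),
    AnalyteSpec("PFDA", 0.01, 0.1),
)


def censor_status(value: float, spec: AnalyteSpec) -> CensorStatus:
    """Classify a raw instrument value against the analyte's limits."""
    if value < spec.lod:
        return BELOW_LOD
    if value < spec.loq:
        return BETWEEN_LOD_LOQ
    return QUANTIFIED


def impute_below_lod(table: pd.DataFrame, spec: AnalyteSpec) -> pd.DataFrame:
    """Substitute below-LOD entries of one analyte by ``LOD / sqrt(2)``.

    ``table`` is a tidy concentration table with columns
    ``participant_id, analyte, value, censor_status``.  Entries between LOD
    and LOQ, and quantified entries, are returned unchanged.
    """
    out = table.copy()
    mask = out["analyte"] == spec.name
    if (out.loc[mask, "value"] < 0).any():
        bad = out.loc[mask & (out["value"] < 0), "participant_id"].iloc[0]
        raise ValueError(f"negative concentration for participant {bad}")
    sub = mask & (out["censor_status"] == BELOW_LOD)
    out.loc[sub, "value"] = spec.lod / math.sqrt(2.0)
    return out


def detection_filter(table: pd.DataFrame, specs: Iterable[AnalyteSpec],
                     min_fraction: float = 0.95,
                     ) -> tuple[list[str], pd.DataFrame]:
    """Retain analytes quantified (>= LOQ) for at least ``min_fraction`` of
    participants.

    Returns the retained analyte names and a per-analyte report with the
    fractions at/above LOD and at/above LOQ (both reported so the
    alternative ">= LOD" reading of the rule is auditable).
    """
    if not (0 < min_fraction <= 1):
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if table.empty:
        raise ValueError("empty concentration table")
    specs = list(specs)
    rows = []
    for spec in specs:
        vals = table.loc[table["analyte"] == spec.name, "value"]
        if vals.empty:
            raise ValueError(f"no entries for analyte {spec.name}")
        frac_lod = float((vals >= spec.lod).mean())
        frac_loq = float((vals >= spec.loq).mean())
        rows.append({"analyte": spec.name, "n": len(vals),
                     "frac_above_lod": frac_lod, "frac_above_loq": frac_loq,
                     "retained": frac_loq >= min_fraction})
    report = pd.DataFrame(rows)
    retained = report.loc[report["retained"], "analyte"].tolist()
    return retained, report


def standardize(values: Sequence[float]) -> tuple[np.ndarray, float, float]:
    """Z-score a vector to mean 0, SD 1 (n-1 denominator).

    Returns ``(z, mean, sd)`` so the transform is invertible:
    ``values = z * sd + mean``.
    """
    arr = np.asarray(values, dtype=float)
    if np.unique(arr).size < 2:
        raise ValueError("cannot standardize a constant vector")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return (arr - mean) / sd, mean, sd


def summarize(values: Sequence[float], spec: AnalyteSpec) -> dict:
    """Median, IQR bounds (linear interpolation) and percent detected.

    Percent detected is the share of values at or above the LOD, on the
    0-100 scale.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty value vector")
    q25, q50, q75 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    return {
        "analyte": spec.name,
        "n": int(arr.size),
        "median": float(q50),
        "iqr_low": float(q25),
        "iqr_high": float(q75),
        "percent_detected": float((arr >= spec.lod).mean() * 100.0),
    }


def summarize_panel(table: pd.DataFrame,
                    specs: Iterable[AnalyteSpec]) -> pd.DataFrame:
    """Descriptive table (one row per analyte) mirroring the usual
    median (IQR) / % detected layout of biomonitoring reports."""
    rows = []
    for spec in specs:
        vals = table.loc[table["analyte"] == spec.name, "value"]
        if vals.empty:
            continue
        rows.append(summarize(vals.to_numpy(), spec))
    return pd.DataFrame(rows)
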