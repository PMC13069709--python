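"""Robustness battery for the fixed-effects exposure model.

* multi-level jackknife influence (individual / subzone / planning area),
* the future-residence negative-control exposure test among movers,
* added-covariate refits,
* the other-land-use confounding scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fe_model import (FEOLSResults, FixedEffectsOLS, ModelSpec,
                       RankDeficientError, SingleClusterError)

__all__ = [
    "InfluenceRecord",
    "jackknife_influence",
    "NegativeControlResult",
    "negative_control_test",
    "covariate_extension",
    "landuse_confounding_scan",
]

_LEVEL_COLS = {"individual": "participant_id",
               "subzone": "subzone_id",
               "planning_area": "planning_area_id"}


@dataclass(frozen=True)
class InfluenceRecord:
    """Leave-one-unit-out change in the exposure coefficient."""

    level: str
    unit_id: str
    beta_full: float
    beta_loo: float

    @property
    def delta(self) -> float:
        return self.beta_loo - self.beta_full


def jackknife_influence(data: pd.DataFrame, spec: ModelSpec, level: str,
                        ) -> pd.DataFrame:
    """Refit the model leaving out each unit at the given level.

    ``level`` is one of ``individual``, ``subzone``, ``planning_area``;
    leaving out a subzone or planning area removes all its observations.
    Returns a table sorted by \\|delta\\| descending, with infeasible refits
    flagged (``ok = False``) rather than fatal.
    """
    if level not in _LEVEL_COLS:
        raise ValueError(f"level must be one of {sorted(_LEVEL_COLS)}")
    col = _LEVEL_COLS[level]
    full = FixedEffectsOLS(data, spec).fit()
    beta_full = full.beta
    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for unit in pd.unique(data[col]):
            reduced = data[data[col] != unit]
            try:
                beta_loo = FixedEffectsOLS(reduced, spec).fit().beta
                ok, note = True, ""
            except (SingleClusterError, RankDeficientError,
                    np.linalg.LinAlgError) as exc:
                beta_loo, ok, note = np.nan, False, str(exc)
            records.append({"level": level, "unit_id": unit,
                            "beta_full": beta_full, "beta_loo": beta_loo,
                            "delta": beta_loo - beta_full, "ok": ok,
                            "note": note})
    out = pd.DataFrame(records)
    out = out.reindex(out["delta"].abs().sort_values(
        ascending=False, na_position="last").index).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class NegativeControlResult:
    """Negative-control fit plus a minimal decision record.

    The interpretation is deliberately non-causal: it states only whether
    the null of no association between the *future*-residence exposure and
    the outcome is rejected at the configured level.  Rejection flags
    possible unmeasured confounding by residential preference.
    """

    result: FEOLSResults
    n_movers: int
    alpha: float

    @property
    def reject(self) -> bool:
        return self.result.p_value < self.alpha

    @property
    def interpretation(self) -> str:
        verdict = ("association detected — unmeasured confounding cannot be "
                   "ruled out" if self.reject else
                   "no association detected at the configured level")
        return (f"negative-control exposure (future residence, movers only, "
                f"n={self.n_movers}): beta={self.result.beta:.4f}, "
                f"p={self.result.p_value:.4f}, alpha={self.alpha}; {verdict}")


def negative_control_test(data: pd.DataFrame, spec: ModelSpec,
                          movers_only: bool = True,
                          future_exposure: str = "future_exposure_k",
                          mover_col: str = "mover",
                          alpha: float = 0.05) -> NegativeControlResult:
    """Refit the model with the future-residence exposure as a placebo.

    Restricted to participants who moved (``movers_only``), since for
    non-movers the future exposure is the baseline exposure.
    """
    if future_exposure not in data.columns:
        raise KeyError(f"missing future exposure column {future_exposure!r}")
    d = data
    if movers_only:
        d = data[data[mover_col].astype(bool)]
        if d.empty:
            raise ValueError("no movers in the analysis table")
    if np.allclose(d[future_exposure], d[spec.exposure]):
        warnings.warn("future exposure identical to baseline exposure for "
                      "all rows; negative control is collinear with the "
                      "design", stacklevel=2)
    res = FixedEffectsOLS(d, spec.with_exposure(future_exposure)).fit()
    return NegativeControlResult(res, n_movers=len(d), alpha=alpha)


def covariate_extension(data: pd.DataFrame, spec: ModelSpec,
                        extra_covariates: list[str]) -> FEOLSResults:
    """Refit with appended covariates (listwise deletion on the additions).

    Collinear additions raise :class:`RankDeficientError` naming the
    columns.
    """
    new_spec = ModelSpec(spec.outcome, spec.exposure,
                         spec.covariates + tuple(extra_covariates),
                         spec.fe_level, spec.cluster_level, spec.ci_level)
    return FixedEffectsOLS(data, new_spec).fit()


def landuse_confounding_scan(data: pd.DataFrame, spec: ModelSpec,
                             other_classes: list[str],
                             exposure_col_pattern: str = "exposure_{cls}_k",
                             ) -> pd.DataFrame:
    """Adjust for each other land-use class's exposure in turn.

    For every listed class the table reports (a) the correlation of that
    class's buffered exposure with the transport-facility exposure and
    (b) the transport coefficient after adding the class's exposure as a
    covariate, with its change versus the base model.  Classes with
    all-zero exposure are skipped with a note.
    """
    base = FixedEffectsOLS(data, spec).fit()
    rows = []
    for cls in other_classes:
        col = exposure_col_pattern.format(cls=cls)
        if col not in data.columns:
            raise KeyError(f"missing exposure column {col!r} for class {cls}")
        if np.allclose(data[col], 0.0):
            rows.append({"land_use_class": cls, "correlation": np.nan,
                         "beta_transport_adjusted": np.nan,
                         "delta_vs_base": np.nan, "se": np.nan,
                         "note": "all-zero exposure; skipped"})
            continue
        corr = float(np.corrcoef(data[spec.exposure], data[col])[0, 1])
        adj = covariate_extension(data, spec, [col])
        rows.append({"land_use_class": cls, "correlation": corr,
                     "beta_transport_adjusted": adj.beta,
                     "delta_vs_base": adj.beta - base.beta,
                     "se": adj.se, "note": ""})
    return pd.DataFrame(rows)
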