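"""Threshold dose-response sweep.

Replaces the continuous exposure with the indicator 1{area > t} over a
grid of thresholds t and refits the fixed-effects model at each one,
keeping covariates, fixed effects and clustering identical to the main
model.  Thresholds whose exposed group is smaller than ``min_exposed``
(or empty, or the whole sample) are flagged rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fe_model import FEOLSResults, FixedEffectsOLS, ModelSpec
from .geoexposure import exposure_indicator

__all__ = ["SweepRow", "SweepResult", "threshold_sweep", "DEFAULT_THRESHOLDS"]

#: 0 to 20,000 m^2 in steps of 2,000 m^2 (11 thresholds).
DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(
    float(t) for t in range(0, 20_001, 2_000))


@dataclass
class SweepRow:
    threshold: float
    result: FEOLSResults | None
    n_exposed: int
    included: bool
    reason: str = ""


@dataclass
class SweepResult:
    """Per-threshold estimates from the indicator sweep."""

    rows: list[SweepRow]
    min_exposed: int

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            r = row.result
            recs.append({
                "threshold_m2": row.threshold,
                "estimate": r.beta if r else np.nan,
                "se": r.se if r else np.nan,
                "ci_low": r.ci_low if r else np.nan,
                "ci_high": r.ci_high if r else np.nan,
                "p": r.p_value if r else np.nan,
                "n_exposed": row.n_exposed,
                "included": row.included,
                "reason": row.reason})
        return pd.DataFrame(recs)

    def plot(self, ax=None):
        """Dot-and-interval plot of the sweep (excluded thresholds hollow)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        df = self.to_frame().dropna(subset=["estimate"])
        for _, r in df.iterrows():
            style = dict(color="k") if r["included"] else dict(
                color="gray", mfc="white")
            ax.errorbar(r["threshold_m2"], r["estimate"],
                        yerr=[[r["estimate"] - r["ci_low"]],
                              [r["ci_high"] - r["estimate"]]],
                        fmt="o", capsize=3, **style)
        ax.axhline(0.0, lw=0.8, color="gray", ls=":")
        ax.set_xlabel("exposure-area threshold t (m$^2$)")
        ax.set_ylabel(r"$\hat\beta^{(t)}$ (ng/mL, exposed vs. not)")
        return ax


def threshold_sweep(data: pd.DataFrame, spec: ModelSpec,
                    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
                    min_exposed: int = 50,
                    exposure_area_col: str = "exposure_m2") -> SweepResult:
    """Fit the FE model with 1{area > t} for each threshold t.

    ``spec`` should be the continuous-exposure model spec; the exposure is
    replaced internally by the indicator column.  ``exposure_area_col``
    names the raw area column in m^2.
    """
    if len(thresholds) == 0:
        raise ValueError("empty threshold list")
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    n = len(data)
    for t in thresholds:
        ind = np.array([exposure_indicator(a, t)
                        for a in data[exposure_area_col]])
        n_exposed = int(ind.sum())
        d = data.copy()
        ind_col = "exposed_gt_t"
        d[ind_col] = ind.astype(float)
        ind_spec = spec.with_exposure(ind_col)
        included, reason, result = True, "", None
        if n_exposed == 0:
            included, reason = False, "no exposed observations"
        elif n_exposed == n:
            included, reason = False, "all observations exposed"
        elif n_exposed < min_exposed:
            included = False
            reason = f"fewer than {min_exposed} exposed"
        if n_exposed not in (0, n):
            try:
                result = FixedEffectsOLS(d, ind_spec).fit()
            except Exception as exc:  # degenerate after FE absorption
                included, reason = False, f"fit failed: {exc}"
        rows.append(SweepRow(t, result, n_exposed, included, reason))
    return SweepResult(rows, min_exposed)
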