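"""Fixed-effects regression of a biomarker concentration on a built-
environment exposure, with cluster-robust inference.

The model is

    y_ic = beta * exposure_ic + gamma' x_i + delta_c + eps_ic

where ``delta_c`` is a separate intercept per administrative area (planning
area, or the finer subzone), absorbed by within-group demeaning rather than
dummy variables.  Standard errors use the CR1 cluster-robust sandwich with
clusters at (by default) the planning-area level, and confidence intervals
use Student-t critical values with G - 1 degrees of freedom, G the number
of clusters.

The public surface follows the Model / Results idiom: build a
:class:`FixedEffectsOLS` from a DataFrame, call :meth:`~FixedEffectsOLS.fit`,
and read estimates, covariance and the ``summary()`` table off the returned
:class:`FEOLSResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelSpec",
    "FixedEffectsOLS",
    "FEOLSResults",
    "within_transform",
    "cluster_robust_vcov",
    "cluster_ci",
    "standardized_coefficient",
    "SingleClusterError",
    "RankDeficientError",
]


class SingleClusterError(ValueError):
    """Cluster-robust inference requires at least two clusters."""


class RankDeficientError(ValueError):
    """The (demeaned) design matrix is rank deficient."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"collinear design columns: {', '.join(self.columns)}")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one regression.

    ``exposure`` names the exposure column (continuous area per 1,000 m^2,
    a z-scored area, or a threshold indicator — the model does not care);
    ``fe_level``/``cluster_level`` name grouping columns, with the cluster
    level at or above the fixed-effect level in the administrative
    hierarchy.
    """

    outcome: str
    exposure: str
    covariates: tuple[str, ...] = ()
    fe_level: str = "subzone_id"
    cluster_level: str = "planning_area_id"
    ci_level: float = 0.95

    def with_exposure(self, exposure: str) -> "ModelSpec":
        return replace(self, exposure=exposure)


def within_transform(y: np.ndarray, X: pd.DataFrame, groups: pd.Series,
                     tol: float = 1e-10,
                     ) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Demean ``y`` and every column of ``X`` within FE groups.

    Columns that are constant within every group (hence absorbed by the
    fixed effects) carry no information after demeaning; they are dropped
    and reported in the third return value.
    """
    codes, _ = pd.factorize(np.asarray(groups))
    counts = np.bincount(codes).astype(float)
    y = np.asarray(y, dtype=float)
    y_sums = np.bincount(codes, weights=y)
    y_t = y - (y_sums / counts)[codes]
    Xm = X.to_numpy(dtype=float)
    sums = np.zeros((counts.size, Xm.shape[1]))
    np.add.at(sums, codes, Xm)
    X_t = pd.DataFrame(Xm - (sums / counts[:, None])[codes],
                       index=X.index, columns=X.columns)
    scale = X.abs().mean().replace(0.0, 1.0)
    dropped = [c for c in X_t.columns
               if X_t[c].abs().max() <= tol * max(1.0, scale[c])]
    if dropped:
        warnings.warn(
            f"columns constant within fixed-effect groups dropped: {dropped}",
            stacklevel=2)
        X_t = X_t.drop(columns=dropped)
    return y_t, X_t, dropped


def cluster_robust_vcov(X: np.ndarray, residuals: np.ndarray,
                        clusters: np.ndarray, correction: str = "CR1",
                        n_absorbed: int = 0) -> np.ndarray:
    """CR1 cluster-robust sandwich covariance of OLS coefficients.

    ``X`` is the (demeaned) design actually regressed on, ``residuals`` the
    OLS residuals, ``clusters`` the cluster labels.  ``n_absorbed`` counts
    parameters absorbed outside ``X`` (the fixed-effect intercepts) and
    enters the small-sample factor
    ``c = [G/(G-1)] * [(N-1)/(N-K)]`` with ``K = X.shape[1] + n_absorbed``.
    With every observation its own cluster this reduces exactly to HC1.
    """
    X = np.asarray(X, dtype=float)
    u = np.asarray(residuals, dtype=float)
    labels, inv = np.unique(np.asarray(clusters), return_inverse=True)
    G = labels.size
    if G < 2:
        raise SingleClusterError(
            "cluster-robust inference needs >= 2 clusters")
    n, k = X.shape
    K = k + n_absorbed
    # cluster-summed scores: S_g = X_g' u_g, accumulated without a python loop
    Xu = X * u[:, None]
    S = np.zeros((G, k))
    np.add.at(S, inv, Xu)
    meat = S.T @ S
    bread = np.linalg.inv(X.T @ X)
    if correction == "CR1":
        c = (G / (G - 1)) * ((n - 1) / (n - K))
    elif correction in (None, "CR0", "none"):
        c = 1.0
    else:
        raise ValueError(f"unknown small-sample correction {correction!r}")
    V = c * bread @ meat @ bread
    return 0.5 * (V + V.T)  # enforce exact symmetry


def cluster_ci(beta: float, se: float, n_clusters: int,
               level: float = 0.95) -> tuple[float, float]:
    """Two-sided confidence interval using Student-t with G-1 df.

    This is the package's single CI convention; it is deliberately exposed
    standalone so printed (beta, SE, G) triples from any source can be
    turned into intervals.
    """
    if n_clusters < 2:
        raise SingleClusterError("need >= 2 clusters for a t interval")
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=n_clusters - 1)
    return beta - tcrit * se, beta + tcrit * se


def standardized_coefficient(beta: float, sd_exposure: float,
                             sd_outcome: float | None = None,
                             ) -> float | tuple[float, float]:
    """Rescale a slope to per-SD units.

    ``beta * sd_exposure`` (with ``sd_exposure`` in the beta's own exposure
    units) is the outcome change per SD of exposure, in ng/mL.  When
    ``sd_outcome`` is given, also returns the fully standardized
    SD-per-SD coefficient ``beta * sd_exposure / sd_outcome``.
    """
    if sd_exposure <= 0:
        raise ValueError(f"sd_exposure must be > 0, got {sd_exposure}")
    per_sd = beta * sd_exposure
    if sd_outcome is None:
        return per_sd
    if sd_outcome <= 0:
        raise ValueError(f"sd_outcome must be > 0, got {sd_outcome}")
    return per_sd, per_sd / sd_outcome


def _expand_design(data: pd.DataFrame, exposure: str,
                   covariates: Sequence[str]) -> pd.DataFrame:
    """Numeric design matrix: exposure first, categoricals dummy-coded
    against their first (sorted) level."""
    cols = [data[exposure].astype(float).rename(exposure)]
    for cov in covariates:
        s = data[cov]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=cov, drop_first=True,
                                     dtype=float)
            cols.extend(dummies[c] for c in dummies.columns)
        else:
            cols.append(s.astype(float))
    return pd.concat(cols, axis=1)


class FixedEffectsOLS:
    """Within-estimator OLS with absorbed administrative-area intercepts.

    Parameters
    ----------
    data
        Analysis table; one row per participant.  Must contain the outcome,
        exposure and covariate columns plus the FE and cluster label
        columns named in the spec.
    spec
        A :class:`ModelSpec`.  Alternatively pass the column names directly
        via :meth:`from_columns`.

    Rows with missing values in any used column are dropped (listwise
    deletion); the count is recorded on the model and the results.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        used = [spec.outcome, spec.exposure, *spec.covariates,
                spec.fe_level, spec.cluster_level]
        missing_cols = [c for c in used if c not in data.columns]
        if missing_cols:
            raise KeyError(f"missing columns: {missing_cols}")
        complete = data[used].notna().all(axis=1)
        self.n_dropped_missing = int((~complete).sum())
        self.data = data.loc[complete].reset_index(drop=True)
        self.spec = spec
        if self.data[spec.cluster_level].nunique() < 2:
            raise SingleClusterError(
                "cluster-robust inference needs >= 2 clusters")

    @classmethod
    def from_columns(cls, data: pd.DataFrame, outcome: str, exposure: str,
                     covariates: Sequence[str] = (),
                     fe_level: str = "subzone_id",
                     cluster_level: str = "planning_area_id",
                     ci_level: float = 0.95) -> "FixedEffectsOLS":
        return cls(data, ModelSpec(outcome, exposure, tuple(covariates),
                                   fe_level, cluster_level, ci_level))

    def fit(self) -> "FEOLSResults":
        spec = self.spec
        d = self.data
        y = d[spec.outcome].astype(float).to_numpy()
        X = _expand_design(d, spec.exposure, spec.covariates)
        groups = d[spec.fe_level]
        n_groups = groups.nunique()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            y_t, X_t, dropped = within_transform(y, X, groups)
        if spec.exposure in dropped:
            raise RankDeficientError([spec.exposure])
        self._check_rank(X_t)
        Xm = X_t.to_numpy(dtype=float)
        beta_hat, *_ = np.linalg.lstsq(Xm, y_t, rcond=None)
        resid = y_t - Xm @ beta_hat

        clusters = d[spec.cluster_level].to_numpy()
        n_clusters = pd.unique(clusters).size
        counts = pd.Series(clusters).value_counts()
        if (counts == 1).mean() > 0.10:
            warnings.warn(
                f"{int((counts == 1).sum())} of {n_clusters} clusters are "
                "singletons; cluster-robust inference may be fragile",
                stacklevel=2)
        vcov = cluster_robust_vcov(Xm, resid, clusters,
                                   n_absorbed=n_groups)
        params = pd.Series(beta_hat, index=X_t.columns)
        bse = pd.Series(np.sqrt(np.diag(vcov)), index=X_t.columns)
        return FEOLSResults(
            model=self, params=params, bse=bse,
            vcov=pd.DataFrame(vcov, index=X_t.columns, columns=X_t.columns),
            resid=resid, nobs=len(d), n_clusters=int(n_clusters),
            n_fixed_effects=int(n_groups), dropped_columns=dropped,
            n_dropped_missing=self.n_dropped_missing)

    def _check_rank(self, X_t: pd.DataFrame) -> None:
        Xm = X_t.to_numpy(dtype=float)
        norms = np.linalg.norm(Xm, axis=0)
        norms[norms == 0] = 1.0
        r = np.linalg.matrix_rank(Xm / norms)
        if r < Xm.shape[1]:
            # name a minimal set of offending columns by greedy QR growth
            bad, kept = [], []
            for j, col in enumerate(X_t.columns):
                cand = Xm[:, kept + [j]]
                if np.linalg.matrix_rank(cand / np.linalg.norm(cand, axis=0)
                                         ) == len(kept) + 1:
                    kept.append(j)
                else:
                    bad.append(col)
            raise RankDeficientError(bad)


@dataclass
class FEOLSResults:
    """Estimates and cluster-robust inference from :class:`FixedEffectsOLS`.

    ``beta``/``se``/``t_stat``/``p_value``/``conf_int()`` refer to the
    exposure coefficient; the full coefficient vector is in ``params``.
    Degrees of freedom for all t inference are ``n_clusters - 1``.
    """

    model: FixedEffectsOLS
    params: pd.Series
    bse: pd.Series
    vcov: pd.DataFrame
    resid: np.ndarray
    nobs: int
    n_clusters: int
    n_fixed_effects: int
    dropped_columns: list[str] = field(default_factory=list)
    n_dropped_missing: int = 0

    @property
    def df_inference(self) -> int:
        return self.n_clusters - 1

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues), df=self.df_inference),
            index=self.params.index)

    # ----- exposure-coefficient accessors -----
    @property
    def exposure_name(self) -> str:
        return self.model.spec.exposure

    @property
    def beta(self) -> float:
        return float(self.params[self.exposure_name])

    @property
    def se(self) -> float:
        return float(self.bse[self.exposure_name])

    @property
    def t_stat(self) -> float:
        return self.beta / self.se

    @property
    def p_value(self) -> float:
        return float(2 * stats.t.sf(abs(self.t_stat), df=self.df_inference))

    def conf_int(self, level: float | None = None) -> pd.DataFrame:
        level = self.model.spec.ci_level if level is None else level
        tcrit = stats.t.ppf(0.5 + level / 2.0, df=self.df_inference)
        lo = self.params - tcrit * self.bse
        hi = self.params + tcrit * self.bse
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})

    @property
    def ci_low(self) -> float:
        return float(self.conf_int().loc[self.exposure_name, "ci_low"])

    @property
    def ci_high(self) -> float:
        return float(self.conf_int().loc[self.exposure_name, "ci_high"])

    def standardized_beta(self) -> float:
        """SD-outcome per SD-exposure, from the analysis sample's SDs."""
        d = self.model.data
        sd_x = d[self.exposure_name].std(ddof=1)
        sd_y = d[self.model.spec.outcome].std(ddof=1)
        _, per_sd = standardized_coefficient(self.beta, sd_x, sd_y)
        return per_sd

    def to_frame(self, label: str = "model") -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame({
            "model": label, "term": self.params.index,
            "estimate": self.params.to_numpy(), "se": self.bse.to_numpy(),
            "df": self.df_inference, "t": self.tvalues.to_numpy(),
            "p": self.pvalues.to_numpy(),
            "ci_low": ci["ci_low"].to_numpy(),
            "ci_high": ci["ci_high"].to_numpy(),
            "n": self.nobs, "n_clusters": self.n_clusters})

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Fixed-effects OLS (within estimator), cluster-robust CR1 SE",
            f"outcome: {spec.outcome}   exposure: {spec.exposure}",
            f"fixed effects: {spec.fe_level} ({self.n_fixed_effects} absorbed)"
            f"   clusters: {spec.cluster_level} (G={self.n_clusters}, "
            f"df={self.df_inference})",
            f"n = {self.nobs}"
            + (f" ({self.n_dropped_missing} dropped, missing covariates)"
               if self.n_dropped_missing else ""),
            "-" * 78,
            f"{'term':<28}{'coef':>10}{'se':>9}{'t':>8}{'p':>8}"
            f"{'[0.025':>9}{'0.975]':>9}",
        ]
        ci = self.conf_int()
        for term in self.params.index:
            lines.append(
                f"{term:<28}{self.params[term]:>10.4f}{self.bse[term]:>9.4f}"
                f"{self.tvalues[term]:>8.2f}{self.pvalues[term]:>8.3f}"
                f"{ci.loc[term, 'ci_low']:>9.3f}{ci.loc[term, 'ci_high']:>9.3f}")
        if self.dropped_columns:
            lines.append(f"dropped (absorbed by FE): {self.dropped_columns}")
        return "\n".join(lines)

    # ----- diagnostics that hang off the results -----
    def jackknife(self, level: str) -> pd.DataFrame:
        from .sensitivity import jackknife_influence
        return jackknife_influence(self.model.data, self.model.spec, level)
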