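"""Synthetic-city generator: a complete, parameterised study world.

Generates (i) a two-level administrative tessellation — planning areas
subdivided into subzones ("neighborhoods") — on a planar rectangular
extent; (ii) land-use parcels, with transport facilities drawn from a
bimodal footprint mixture (small petrol kiosks vs. large bus depots);
(iii) postcode centroid residences and participants with covariates and
residential mobility; and (iv) censored biomarker outcomes from a known
linear data-generating process

    y_i = intercept + beta * (exposure_i / 1000 m^2) + gamma' x_i
          + delta_subzone(i) + eps_i .

Subzone intercepts (not planning-area intercepts) carry the spatial
confounding in the default DGP: delta_s is coupled to the subzone's mean
exposure, so a planning-area fixed-effects fit is biased while a subzone
fixed-effects fit is not — the granularity contrast the analysis modules
are designed to exercise.

Randomness uses one master seed with independent named substreams per
component (geography, parcels, postcodes, participants, outcome noise),
so redrawing one component's noise does not perturb the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.random import Generator, default_rng
from shapely.geometry import Polygon, box

from .biomarker_prep import (BELOW_LOD, DEFAULT_PANEL, AnalyteSpec,
                             censor_status)
from .geoexposure import Parcel, Residence, exposure_table

__all__ = [
    "AdminMap",
    "DGPParams",
    "SecondaryAnalyte",
    "Participant",
    "CityConfig",
    "SyntheticCity",
    "ConfigurationError",
    "GenerationError",
    "generate_admin_hierarchy",
    "generate_parcels",
    "generate_postcodes",
    "generate_participants",
    "simulate_outcomes",
    "generate_city",
    "DEFAULT_LAND_USE_MIX",
    "DEFAULT_COVARIATE_MODEL",
    "DEFAULT_GAMMA",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


class GenerationError(RuntimeError):
    """The generator could not satisfy the configuration (e.g. packing)."""


# --------------------------------------------------------------------------
# administrative hierarchy
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AdminMap:
    """Two-level administrative geography on a rectangular extent."""

    planning_areas: tuple[tuple[str, Polygon], ...]
    subzones: tuple[tuple[str, str, Polygon], ...]  # (subzone, parent, poly)
    extent: tuple[float, float, float, float]       # xmin, ymin, xmax, ymax

    @property
    def subzone_parent(self) -> dict[str, str]:
        return {sz: pa for sz, pa, _ in self.subzones}

    def subzone_of(self, x: float, y: float) -> tuple[str, str]:
        """Labels of the subzone (and its planning area) containing a point."""
        from shapely.geometry import Point
        pt = Point(x, y)
        for sz, pa, poly in self.subzones:
            # covers() so points on shared edges resolve to the first zone
            if poly.covers(pt):
                return sz, pa
        raise ValueError(f"point ({x}, {y}) outside every subzone")


def _partition_rect(rect: tuple[float, float, float, float], n: int,
                    rng: Generator, jitter: float = 0.25,
                    ) -> list[tuple[float, float, float, float]]:
    """Recursively slice a rectangle into ``n`` sub-rectangles.

    Splits the longer side at a size-proportional position with a bounded
    random jitter; yields exact tessellations (shared edges, no gaps).
    """
    if n == 1:
        return [rect]
    n1 = n // 2
    frac = n1 / n * (1.0 + jitter * (rng.random() - 0.5))
    frac = min(max(frac, 0.15), 0.85)
    xmin, ymin, xmax, ymax = rect
    if (xmax - xmin) >= (ymax - ymin):
        cut = xmin + frac * (xmax - xmin)
        a, b = (xmin, ymin, cut, ymax), (cut, ymin, xmax, ymax)
    else:
        cut = ymin + frac * (ymax - ymin)
        a, b = (xmin, ymin, xmax, cut), (xmin, cut, xmax, ymax)
    return (_partition_rect(a, n1, rng, jitter)
            + _partition_rect(b, n - n1, rng, jitter))


def generate_admin_hierarchy(n_planning_areas: int = 33,
                             n_subzones: int = 147,
                             extent: tuple[float, float] = (30_000.0, 20_000.0),
                             seed: int = 0) -> AdminMap:
    """Tessellate the extent into planning areas, each split into subzones.

    ``n_subzones`` is the total; it is distributed across planning areas as
    evenly as integer arithmetic allows (e.g. 147 over 33 areas gives a mix
    of 4 and 5 subzones per area).  Deterministic given the seed.
    """
    if n_planning_areas < 1 or n_subzones < n_planning_areas:
        raise ConfigurationError(
            f"need n_planning_areas >= 1 and n_subzones >= n_planning_areas, "
            f"got {n_planning_areas}, {n_subzones}")
    w, h = extent
    if w <= 0 or h <= 0:
        raise ConfigurationError(f"degenerate extent {extent}")
    rng = default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    outer = (0.0, 0.0, float(w), float(h))
    pa_rects = _partition_rect(outer, n_planning_areas, rng)
    base, extra = divmod(n_subzones, n_planning_areas)
    # planning areas receiving one extra subzone, chosen by the same stream
    extra_idx = set(rng.choice(n_planning_areas, size=extra, replace=False))
    planning_areas, subzones = [], []
    for i, r in enumerate(pa_rects):
        pa_id = f"PA{i:02d}"
        planning_areas.append((pa_id, box(*r)))
        k = base + (1 if i in extra_idx else 0)
        for j, sr in enumerate(_partition_rect(r, k, rng)):
            subzones.append((f"{pa_id}_SZ{j}", pa_id, box(*sr)))
    return AdminMap(tuple(planning_areas), tuple(subzones), outer)


# --------------------------------------------------------------------------
# parcels
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParcelComponent:
    """One mixture component of a land-use class's footprint distribution."""

    n: int
    area_low: float
    area_high: float
    label: str = ""

    def __post_init__(self):
        if self.n < 0 or self.area_low <= 0 or self.area_high < self.area_low:
            raise ConfigurationError(f"invalid parcel component {self}")


#: Default land-use mix.  Transport facilities are the bimodal mixture of
#: small petrol kiosks (1,000-4,000 m^2) and large bus depots/terminals
#: (10,000-50,000 m^2); other classes exist for descriptives and the
#: land-use confounding scan.
DEFAULT_LAND_USE_MIX: dict[str, tuple[ParcelComponent, ...]] = {
    "transport_facility": (ParcelComponent(160, 1_000.0, 4_000.0, "kiosk"),
                           ParcelComponent(64, 10_000.0, 50_000.0, "depot")),
    "industrial": (ParcelComponent(40, 5_000.0, 60_000.0),),
    "business2_white": (ParcelComponent(60, 2_000.0, 20_000.0),),
    "residential": (ParcelComponent(150, 2_000.0, 15_000.0),),
    "park": (ParcelComponent(50, 5_000.0, 40_000.0),),
}


def generate_parcels(admin_map: AdminMap,
                     land_use_mix: Mapping[str, Sequence[ParcelComponent]]
                     = DEFAULT_LAND_USE_MIX,
                     seed: int = 0,
                     max_fill_fraction: float = 0.25,
                     max_attempts: int = 2_000) -> list[Parcel]:
    """Place rectangular parcels uniformly in the extent.

    Footprint areas are drawn uniformly within each component's range, with
    a random aspect ratio; parcels of the same class are kept pairwise
    disjoint by rejection sampling.  Requested total area above
    ``max_fill_fraction`` of the extent raises a generation error naming
    the class.
    """
    xmin, ymin, xmax, ymax = admin_map.extent
    extent_area = (xmax - xmin) * (ymax - ymin)
    rng = default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    parcels: list[Parcel] = []
    for cls in sorted(land_use_mix):
        components = land_use_mix[cls]
        requested = sum(c.n * (c.area_low + c.area_high) / 2.0
                        for c in components)
        if requested > max_fill_fraction * extent_area:
            raise GenerationError(
                f"class {cls!r}: requested parcel area {requested:.0f} m^2 "
                f"exceeds {max_fill_fraction:.0%} of the extent")
        placed: list[Polygon] = []
        idx = 0
        for comp in components:
            for _ in range(comp.n):
                area = rng.uniform(comp.area_low, comp.area_high)
                for _attempt in range(max_attempts):
                    aspect = rng.uniform(0.5, 2.0)
                    pw = math.sqrt(area * aspect)
                    ph = area / pw
                    if pw > xmax - xmin or ph > ymax - ymin:
                        continue
                    cx = rng.uniform(xmin + pw / 2, xmax - pw / 2)
                    cy = rng.uniform(ymin + ph / 2, ymax - ph / 2)
                    cand = box(cx - pw / 2, cy - ph / 2,
                               cx + pw / 2, cy + ph / 2)
                    if not any(cand.intersects(p) for p in placed):
                        placed.append(cand)
                        parcels.append(Parcel(f"{cls}_{idx}", cls, cand))
                        idx += 1
                        break
                else:
                    raise GenerationError(
                        f"class {cls!r}: could not place a "
                        f"{area:.0f} m^2 parcel after {max_attempts} tries")
    return parcels


# --------------------------------------------------------------------------
# postcodes and participants
# --------------------------------------------------------------------------

def generate_postcodes(admin_map: AdminMap, n_postcodes: int = 500,
                       seed: int = 0) -> list[Residence]:
    """Sample postcode centroid points uniformly over the extent and label
    each with its containing subzone and planning area."""
    if n_postcodes < 1:
        raise ConfigurationError("need at least one postcode")
    rng = default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    xmin, ymin, xmax, ymax = admin_map.extent
    out = []
    for i in range(n_postcodes):
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        sz, pa = admin_map.subzone_of(x, y)
        out.append(Residence(f"PC{i:04d}", (x, y), sz, pa))
    return out


@dataclass(frozen=True)
class Participant:
    """One study participant: residences per wave plus covariates.

    ``latent`` is an unmeasured individual factor; it is inert unless the
    DGP's confounded-preference switch links it to both residence choice
    and the outcome.
    """

    participant_id: str
    residences: dict[str, Residence]          # wave -> Residence
    covariates: dict[str, object]
    latent: float = 0.0

    @property
    def mover(self) -> bool:
        fut = self.residences.get("future")
        return (fut is not None
                and fut.postcode_id != self.residences["baseline"].postcode_id)


#: Covariate sampling spec: name -> ("normal", mean, sd) |
#: ("count", lambda) | ("categorical", levels, probs[, prob_missing]).
DEFAULT_COVARIATE_MODEL: dict[str, tuple] = {
    "age": ("normal", 30.7, 5.1),
    "parity": ("count", 0.9),
    "ethnicity": ("categorical", ["chinese", "malay", "indian"],
                  [0.56, 0.26, 0.18]),
    "education": ("categorical",
                  ["secondary_or_less", "post_secondary", "university"],
                  [0.35, 0.40, 0.25]),
    "occupation": ("categorical", ["not_employed", "service", "professional"],
                   [0.30, 0.35, 0.35]),
    "housing_type": ("categorical", ["public_small", "public_large",
                                     "private"], [0.35, 0.45, 0.20]),
    "marital_status": ("categorical", ["married", "other"], [0.92, 0.08]),
    "birthplace": ("categorical", ["local", "elsewhere"], [0.70, 0.30]),
    "income": ("categorical", ["low", "middle", "high"],
               [0.30, 0.45, 0.25], 0.25),
}

#: True covariate effects (ng/mL per unit / per level vs. the reference).
DEFAULT_GAMMA: dict[str, object] = {
    "age": 0.06,
    "parity": -0.4,
    "ethnicity": {"malay": 1.2, "indian": 0.8},
    "education": {"post_secondary": -0.5, "university": -1.0},
    "occupation": {"service": 0.3, "professional": 0.5},
    "housing_type": {"public_large": -0.3, "private": -0.8},
    "marital_status": {"other": 0.4},
    "birthplace": {"elsewhere": 0.9},
    "income": {"middle": -0.3, "high": -0.6},
}


def _sample_covariate(spec: tuple, n: int, rng: Generator) -> np.ndarray:
    kind = spec[0]
    if kind == "normal":
        return rng.normal(spec[1], spec[2], size=n)
    if kind == "count":
        return rng.poisson(spec[1], size=n).astype(float)
    if kind == "categorical":
        levels, probs = spec[1], spec[2]
        vals = rng.choice(np.asarray(levels, dtype=object), size=n,
                          p=np.asarray(probs, dtype=float))
        if len(spec) > 3 and spec[3] > 0:
            vals = vals.copy()
            vals[rng.random(n) < spec[3]] = None
        return vals
    raise ConfigurationError(f"unknown covariate kind {kind!r}")


def generate_participants(n: int, admin_map: AdminMap,
                          postcodes: Sequence[Residence],
                          covariate_model: Mapping[str, tuple]
                          = DEFAULT_COVARIATE_MODEL,
                          mover_fraction: float = 0.5,
                          seed: int = 0,
                          preference_strength: float = 0.0,
                          postcode_scores: Mapping[str, float] | None = None,
                          ) -> list[Participant]:
    """Assign residences, mobility and covariates to ``n`` participants.

    Baseline postcodes are drawn uniformly (several participants may share
    one centroid).  A ``mover_fraction`` subset receives a distinct future
    postcode: uniformly among the other postcodes by default, or — when
    ``preference_strength`` > 0 and per-postcode ``postcode_scores`` are
    supplied — with log-weights ``preference_strength * latent_i * score``,
    the confounded-preference mechanism used to demonstrate negative-
    control detection.
    """
    if n < 1:
        raise ConfigurationError("need n >= 1 participants")
    if not postcodes:
        raise ConfigurationError("need at least one postcode")
    if not (0.0 <= mover_fraction <= 1.0):
        raise ConfigurationError(
            f"mover_fraction must be in [0, 1], got {mover_fraction}")
    rng = default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    pcs = list(postcodes)
    base_idx = rng.integers(0, len(pcs), size=n)
    latent = rng.normal(size=n)
    cov_draws = {name: _sample_covariate(spec, n, rng)
                 for name, spec in covariate_model.items()}
    n_movers = int(round(n * mover_fraction))
    mover_ids = set(rng.choice(n, size=n_movers, replace=False)) \
        if n_movers else set()
    if postcode_scores is not None:
        scores = np.array([postcode_scores[p.postcode_id] for p in pcs])
    else:
        scores = np.zeros(len(pcs))
    participants = []
    for i in range(n):
        home = pcs[base_idx[i]]
        residences = {"baseline": home, "future": home}
        if i in mover_ids and len(pcs) > 1:
            logw = preference_strength * latent[i] * scores
            w = np.exp(logw - logw.max())
            w[base_idx[i]] = 0.0  # movers move: future differs from baseline
            w /= w.sum()
            residences["future"] = pcs[rng.choice(len(pcs), p=w)]
        participants.append(Participant(
            participant_id=f"P{i:04d}", residences=residences,
            covariates={k: v[i] for k, v in cov_draws.items()},
            latent=float(latent[i])))
    return participants


# --------------------------------------------------------------------------
# outcomes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SecondaryAnalyte:
    """Own-scale DGP for a non-primary analyte (all in ng/mL)."""

    intercept: float
    beta: float          # per 1,000 m^2 exposure
    sigma: float         # residual SD; subzone SD and gamma scale with it


@dataclass(frozen=True)
class DGPParams:
    """Known parameters of the outcome-generating process.

    ``beta_true`` is in ng/mL per 1,000 m^2 of buffered transport-facility
    area; ``subzone_confounding`` couples subzone intercepts to the
    subzone's mean exposure (per 1,000 m^2), which biases planning-area FE
    fits but is absorbed by subzone FE; ``latent_loading`` adds the
    unmeasured individual factor to the outcome (used together with the
    generator's confounded-preference switch).
    """

    beta_true: float = 0.15
    gamma_true: Mapping[str, object] = field(
        default_factory=lambda: dict(DEFAULT_GAMMA))
    intercept: float = 20.0
    sigma_subzone: float = 2.0
    sigma_eps: float = 8.0
    subzone_confounding: float = 0.10
    latent_loading: float = 0.0
    analytes: tuple[AnalyteSpec, ...] = DEFAULT_PANEL[:4]  # PFBS..PFOA
    secondary: Mapping[str, SecondaryAnalyte] = field(default_factory=lambda: {
        "PFBA": SecondaryAnalyte(0.9, 0.030, 0.45),
        "PFNA": SecondaryAnalyte(0.6, 0.0008, 0.25),
        "PFOA": SecondaryAnalyte(3.5, 0.005, 1.2),
    })
    mover_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.sigma_subzone < 0 or self.sigma_eps < 0:
            raise ConfigurationError("SDs must be >= 0")
        if not (0.0 <= self.mover_fraction <= 1.0):
            raise ConfigurationError(
                f"mover_fraction must be in [0, 1], got {self.mover_fraction}")


def _covariate_contribution(cov: Mapping[str, object],
                            gamma: Mapping[str, object]) -> float:
    total = 0.0
    for name, eff in gamma.items():
        v = cov.get(name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        if isinstance(eff, Mapping):
            total += float(eff.get(v, 0.0))
        else:
            total += float(eff) * float(v)
    return total


def simulate_outcomes(participants: Sequence[Participant],
                      exposures: pd.DataFrame,
                      dgp: DGPParams) -> pd.DataFrame:
    """Draw censored biomarker concentrations from the linear DGP.

    ``exposures`` is a tidy table (participant_id, wave, land_use_class,
    area_m2) that must contain a baseline transport-facility record for
    every participant.  Returns a tidy concentration table with columns
    ``participant_id, analyte, value, censor_status, true_value``; the
    reported ``value`` is the instrument reading floored at zero, while
    ``true_value`` keeps the uncensored draw for oracle tests.
    """
    rng = default_rng(np.random.SeedSequence(dgp.seed, spawn_key=(4,)))
    base = exposures[(exposures["wave"] == "baseline")
                     & (exposures["land_use_class"] == "transport_facility")]
    expo = dict(zip(base["participant_id"], base["area_m2"]))
    missing = [p.participant_id for p in participants
               if p.participant_id not in expo]
    if missing:
        raise ValueError(
            f"missing baseline exposure record for participant {missing[0]}")

    pids = [p.participant_id for p in participants]
    x_k = np.array([expo[pid] for pid in pids]) / 1_000.0  # per 1,000 m^2
    subzone = np.array([p.residences["baseline"].subzone_id
                        for p in participants])
    sz_levels, sz_idx = np.unique(subzone, return_inverse=True)
    sz_mean_expo = np.zeros(sz_levels.size)
    np.add.at(sz_mean_expo, sz_idx, x_k)
    sz_mean_expo /= np.bincount(sz_idx)
    # subzone intercepts: iid noise plus the exposure-coupled confounder
    sz_noise = rng.normal(size=sz_levels.size)
    delta_primary = (dgp.sigma_subzone * sz_noise
                     + dgp.subzone_confounding * sz_mean_expo)
    gamma_x = np.array([_covariate_contribution(p.covariates, dgp.gamma_true)
                        for p in participants])
    latent = np.array([p.latent for p in participants])

    rows = []
    for spec in dgp.analytes:
        if spec.name in dgp.secondary:
            s = dgp.secondary[spec.name]
            scale = s.sigma / dgp.sigma_eps if dgp.sigma_eps > 0 else 0.0
            mu = (s.intercept + s.beta * x_k + scale * gamma_x
                  + scale * dgp.latent_loading * latent
                  + scale * dgp.sigma_subzone * sz_noise[sz_idx])
            sigma = s.sigma
        else:  # primary analyte on its own stated scale
            mu = (dgp.intercept + dgp.beta_true * x_k + gamma_x
                  + dgp.latent_loading * latent + delta_primary[sz_idx])
            sigma = dgp.sigma_eps
        true = mu + rng.normal(scale=sigma, size=len(pids)) \
            if sigma > 0 else mu.copy()
        reported = np.maximum(true, 0.0)
        for pid, t, v in zip(pids, true, reported):
            rows.append({"participant_id": pid, "analyte": spec.name,
                         "value": float(v),
                         "censor_status": censor_status(float(v), spec),
                         "true_value": float(t)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# whole-city convenience
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CityConfig:
    """Study-scale configuration: counts mirror the cohort setting the
    package emulates (33 planning areas, 147 subzones, 784 participants)."""

    n_planning_areas: int = 33
    n_subzones: int = 147
    extent: tuple[float, float] = (30_000.0, 20_000.0)
    n_postcodes: int = 500
    n_participants: int = 784
    land_use_mix: Mapping[str, tuple[ParcelComponent, ...]] = field(
        default_factory=lambda: dict(DEFAULT_LAND_USE_MIX))
    covariate_model: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MODEL))
    radius: float = 500.0
    preference_strength: float = 0.0
    seed: int = 0


@dataclass
class SyntheticCity:
    """A generated study: geography, parcels, people, exposures, outcomes."""

    config: CityConfig
    dgp: DGPParams
    admin: AdminMap
    parcels: list[Parcel]
    postcodes: list[Residence]
    participants: list[Participant]
    exposures: pd.DataFrame            # participant x wave x class
    concentrations: pd.DataFrame
    postcode_exposures: pd.DataFrame = None  # postcode x class cache

    def participants_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            base = p.residences["baseline"]
            fut = p.residences["future"]
            row = {"participant_id": p.participant_id,
                   "postcode_id": base.postcode_id,
                   "subzone_id": base.subzone_id,
                   "planning_area_id": base.planning_area_id,
                   "future_postcode_id": fut.postcode_id,
                   "mover": p.mover}
            row.update(p.covariates)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_analysis_frame(self, analyte: str = "PFBS",
                          impute: bool = True,
                          land_use_class: str = "transport_facility",
                          ) -> pd.DataFrame:
        """Merged per-participant analysis table.

        Exposure columns are in units of 1,000 m^2 (``exposure_k``
        baseline, ``future_exposure_k`` future wave); the outcome column is
        named after the analyte, below-LOD entries imputed at LOD/sqrt(2)
        unless ``impute=False``.
        """
        from .biomarker_prep import impute_below_lod
        conc = self.concentrations[
            self.concentrations["analyte"] == analyte].copy()
        if impute:
            spec = next(a for a in self.dgp.analytes if a.name == analyte)
            conc = impute_below_lod(conc, spec)
        out = self.participants_frame()
        wide = {}
        for wave, colname in (("baseline", "exposure_k"),
                              ("future", "future_exposure_k")):
            sub = self.exposures[
                (self.exposures["wave"] == wave)
                & (self.exposures["land_use_class"] == land_use_class)]
            wide[colname] = dict(zip(sub["participant_id"], sub["area_m2"]))
        out["exposure_k"] = out["participant_id"].map(
            wide["exposure_k"]) / 1_000.0
        out["future_exposure_k"] = out["participant_id"].map(
            wide["future_exposure_k"]) / 1_000.0
        out["exposure_m2"] = out["exposure_k"] * 1_000.0
        out[analyte] = out["participant_id"].map(
            dict(zip(conc["participant_id"], conc["value"])))
        out[f"{analyte}_true"] = out["participant_id"].map(
            dict(zip(conc["participant_id"], conc["true_value"])))
        return out

    def resimulate(self, seed: int) -> "SyntheticCity":
        """Redraw outcome noise only (same geography, parcels, people)."""
        dgp = replace(self.dgp, seed=seed)
        conc = simulate_outcomes(self.participants, self.exposures, dgp)
        return replace_city(self, dgp=dgp, concentrations=conc)

    def resample_participants(self, seed: int,
                              preference_strength: float | None = None,
                              latent_loading: float | None = None,
                              ) -> "SyntheticCity":
        """Redraw participants (residences, mobility, covariates) and
        outcomes on the fixed geography, reusing cached postcode exposures.

        Used for replicate studies of the mobility-dependent analyses
        (negative control): each replicate gets fresh residence draws
        without re-running any geometry.
        """
        pref = (self.config.preference_strength
                if preference_strength is None else preference_strength)
        load = (self.dgp.latent_loading
                if latent_loading is None else latent_loading)
        scores = None
        if pref > 0:
            tf = self.postcode_exposures[
                self.postcode_exposures["land_use_class"]
                == "transport_facility"]
            vals = tf.set_index("postcode_id")["area_m2"]
            sd = vals.std(ddof=1)
            scores = ((vals - vals.mean()) / (sd if sd > 0 else 1.0)).to_dict()
        participants = generate_participants(
            self.config.n_participants, self.admin, self.postcodes,
            covariate_model=self.config.covariate_model,
            mover_fraction=self.dgp.mover_fraction, seed=seed,
            preference_strength=pref, postcode_scores=scores)
        exposures = _exposures_from_cache(participants,
                                          self.postcode_exposures,
                                          self.config.radius)
        dgp = replace(self.dgp, seed=seed, latent_loading=load)
        conc = simulate_outcomes(participants, exposures, dgp)
        return replace_city(self, dgp=dgp, participants=participants,
                            exposures=exposures, concentrations=conc)


def replace_city(city: SyntheticCity, **kw) -> SyntheticCity:
    from dataclasses import replace as _r
    return _r(city, **kw)


def postcode_exposure_scores(postcodes: Sequence[Residence],
                             parcels: Sequence[Parcel],
                             radius: float = 500.0) -> dict[str, float]:
    """Z-scored transport-facility exposure per postcode (used as the
    preference score in the confounded-mobility variant)."""
    res_map = {p.postcode_id: {"baseline": p} for p in postcodes}
    tab = exposure_table(res_map, parcels, radius=radius)
    vals = tab.set_index("participant_id")["area_m2"]
    sd = vals.std(ddof=1)
    z = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
    return z.to_dict()


def _exposures_from_cache(participants: Sequence[Participant],
                          postcode_exposures: pd.DataFrame,
                          radius: float) -> pd.DataFrame:
    """Participant x wave x class exposure table by postcode lookup."""
    lut = {(r.postcode_id, r.land_use_class): r.area_m2
           for r in postcode_exposures.itertuples()}
    rows = []
    classes = postcode_exposures["land_use_class"].unique()
    for p in participants:
        for wave in ("baseline", "future"):
            pc = p.residences[wave].postcode_id
            for cls in classes:
                rows.append({"participant_id": p.participant_id,
                             "wave": wave, "land_use_class": cls,
                             "radius_m": radius,
                             "area_m2": lut[(pc, cls)]})
    return pd.DataFrame(rows)


def generate_city(config: CityConfig = CityConfig(),
                  dgp: DGPParams | None = None) -> SyntheticCity:
    """Generate the full synthetic study from one master seed.

    The master seed feeds independent substreams (geography, parcels,
    postcodes, participants, outcome noise), so e.g. redrawing outcomes
    leaves the map untouched.
    """
    dgp = dgp if dgp is not None else DGPParams(seed=config.seed)
    admin = generate_admin_hierarchy(config.n_planning_areas,
                                     config.n_subzones, config.extent,
                                     seed=config.seed)
    parcels = generate_parcels(admin, config.land_use_mix, seed=config.seed)
    postcodes = generate_postcodes(admin, config.n_postcodes,
                                   seed=config.seed)
    # exposure geometry once per postcode; participants share centroids
    pc_map = {r.postcode_id: {"baseline": r} for r in postcodes}
    pc_expo = exposure_table(pc_map, parcels, radius=config.radius,
                             land_use_classes=tuple(config.land_use_mix))
    pc_expo = pc_expo.rename(columns={"participant_id": "postcode_id"}
                             ).drop(columns=["wave"])
    scores = None
    if config.preference_strength > 0:
        tf = pc_expo[pc_expo["land_use_class"] == "transport_facility"]
        vals = tf.set_index("postcode_id")["area_m2"]
        sd = vals.std(ddof=1)
        scores = ((vals - vals.mean()) / (sd if sd > 0 else 1.0)).to_dict()
    participants = generate_participants(
        config.n_participants, admin, postcodes,
        covariate_model=config.covariate_model,
        mover_fraction=dgp.mover_fraction, seed=config.seed,
        preference_strength=config.preference_strength,
        postcode_scores=scores)
    exposures = _exposures_from_cache(participants, pc_expo, config.radius)
    concentrations = simulate_outcomes(participants, exposures, dgp)
    return SyntheticCity(config, dgp, admin, parcels, postcodes,
                         participants, exposures, concentrations,
                         postcode_exposures=pc_expo)
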