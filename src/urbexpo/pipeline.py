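"""End-to-end pipeline: simulate -> exposure -> prep -> models -> sweep ->
sensitivity, from a single validated config with one master seed.

Every run writes a manifest of output files with SHA-256 hashes; the same
config and seed reproduce the same manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import biomarker_prep, io as geo_io
from .dose_response import DEFAULT_THRESHOLDS, threshold_sweep
from .fe_model import FixedEffectsOLS, ModelSpec
from .geoexposure import landuse_summary
from .sensitivity import (jackknife_influence, landuse_confounding_scan,
                          negative_control_test)
from .synthetic_city import (CityConfig, ConfigurationError, DGPParams,
                             SyntheticCity, generate_city)

from .studies import MODEL_COVARIATES  # Models 1/2 covariates; Model 3 adds income

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_config",
           "MODEL_COVARIATES"]

log = logging.getLogger("urbexpo")


@dataclass
class PipelineConfig:
    """Validated configuration for one full run."""

    seed: int = 0
    out_dir: str = "urbexpo_run"
    radius: float = 500.0
    analyte: str = "PFBS"
    land_use_class: str = "transport_facility"
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    min_exposed: int = 50
    n_participants: int = 784
    n_planning_areas: int = 33
    n_subzones: int = 147
    n_postcodes: int = 500
    mover_fraction: float = 0.5
    preference_strength: float = 0.0
    jackknife_levels: tuple[str, ...] = ("subzone", "planning_area")
    scan_classes: tuple[str, ...] = ("industrial", "business2_white",
                                     "residential", "park")
    detection_min_fraction: float = 0.95

    def validate(self) -> None:
        checks = [
            ("radius", self.radius is not None and self.radius > 0),
            ("seed", isinstance(self.seed, int)),
            ("n_participants", self.n_participants >= 1),
            ("mover_fraction", 0.0 <= self.mover_fraction <= 1.0),
            ("thresholds", len(self.thresholds) > 0),
            ("min_exposed", self.min_exposed >= 0),
            ("detection_min_fraction",
             0 < self.detection_min_fraction <= 1),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise ConfigurationError(
                f"invalid or missing config field(s): {', '.join(bad)}")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config; unknown keys are rejected by name."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
    for key in ("thresholds", "jackknife_levels", "scan_classes"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


@dataclass
class RunReport:
    config: PipelineConfig
    seed: int
    manifest: dict[str, str] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    failed_stage: str | None = None

    def add_file(self, path: Path) -> None:
        self.manifest[path.name] = hashlib.sha256(
            path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, report: RunReport,
               round_decimals: int | None = 3) -> None:
    out = df.copy()
    if round_decimals is not None:
        for col in out.select_dtypes("float").columns:
            out[col] = out[col].round(round_decimals)
    out.to_csv(path, index=False)
    report.add_file(path)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage and write all outputs under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config, seed=config.seed)
    t0 = time.time()

    def stage(name):
        log.info("stage %s (t=%.1fs)", name, time.time() - t0)
        report.stages.append({"stage": name, "t": round(time.time() - t0, 2)})

    try:
        stage("simulate")
        city_cfg = CityConfig(
            n_planning_areas=config.n_planning_areas,
            n_subzones=config.n_subzones,
            n_postcodes=config.n_postcodes,
            n_participants=config.n_participants,
            radius=config.radius,
            preference_strength=config.preference_strength,
            seed=config.seed)
        dgp = DGPParams(seed=config.seed,
                        mover_fraction=config.mover_fraction)
        city = generate_city(city_cfg, dgp)
        geo_io.write_parcels_geojson(city.parcels, out / "parcels.geojson")
        report.add_file(out / "parcels.geojson")
        geo_io.write_admin_geojson(city.admin, out / "admin.geojson")
        report.add_file(out / "admin.geojson")
        geo_io.write_residences_csv(city.postcodes, out / "postcodes.csv")
        report.add_file(out / "postcodes.csv")
        _write_csv(city.participants_frame(), out / "participants.csv",
                   report)
        (out / "dgp.yaml").write_text(yaml.safe_dump({
            "beta_true": dgp.beta_true, "sigma_subzone": dgp.sigma_subzone,
            "sigma_eps": dgp.sigma_eps, "intercept": dgp.intercept,
            "subzone_confounding": dgp.subzone_confounding,
            "mover_fraction": dgp.mover_fraction, "seed": dgp.seed}))
        report.add_file(out / "dgp.yaml")

        stage("exposure")
        _write_csv(city.exposures, out / "exposures.csv", report)
        summary = landuse_summary(city.parcels, city.postcodes,
                                  config.radius)
        _write_csv(summary, out / "landuse_summary.csv", report, 6)

        stage("prep")
        conc = city.concentrations
        retained, det_report = biomarker_prep.detection_filter(
            conc, city.dgp.analytes,
            min_fraction=config.detection_min_fraction)
        _write_csv(det_report, out / "detection_report.csv", report, 4)
        imputed = conc
        for spec in city.dgp.analytes:
            imputed = biomarker_prep.impute_below_lod(imputed, spec)
        _write_csv(imputed.drop(columns=["true_value"]),
                   out / "concentrations.csv", report, 6)
        _write_csv(biomarker_prep.summarize_panel(imputed, city.dgp.analytes),
                   out / "biomarker_summary.csv", report, 4)
        if config.analyte not in retained:
            log.warning("analyte %s failed the detection filter; "
                        "continuing with it regardless", config.analyte)

        stage("fit")
        table = city.to_analysis_frame(config.analyte,
                                       land_use_class=config.land_use_class)
        specs = {
            "model1": ModelSpec(config.analyte, "exposure_k",
                                MODEL_COVARIATES, fe_level="planning_area_id"),
            "model2": ModelSpec(config.analyte, "exposure_k",
                                MODEL_COVARIATES, fe_level="subzone_id"),
            "model3": ModelSpec(config.analyte, "exposure_k",
                                MODEL_COVARIATES + ("income",),
                                fe_level="subzone_id"),
        }
        frames, results = [], {}
        for label, spec in specs.items():
            res = FixedEffectsOLS(table, spec).fit()
            results[label] = res
            frames.append(res.to_frame(label))
        _write_csv(pd.concat(frames), out / "models.csv", report, 6)
        forest = [
            f"{label:<8} beta={r.beta:8.4f}  se={r.se:7.4f}  "
            f"95% CI [{r.ci_low:7.4f}, {r.ci_high:7.4f}]  p={r.p_value:.4f}  "
            f"n={r.nobs}  G={r.n_clusters}  std_beta={r.standardized_beta():.4f}"
            for label, r in results.items()]
        (out / "forest.txt").write_text("\n".join(forest) + "\n")
        report.add_file(out / "forest.txt")

        stage("sweep")
        sweep = threshold_sweep(table, specs["model2"],
                                thresholds=config.thresholds,
                                min_exposed=config.min_exposed)
        _write_csv(sweep.to_frame(), out / "sweep.csv", report, 6)

        stage("sensitivity")
        for level in config.jackknife_levels:
            infl = jackknife_influence(table, specs["model2"], level)
            _write_csv(infl, out / f"influence_{level}.csv", report, 6)
        nc = negative_control_test(table, specs["model2"])
        _write_csv(nc.result.to_frame("negative_control"),
                   out / "negative_control.csv", report, 6)
        (out / "negative_control.txt").write_text(nc.interpretation + "\n")
        report.add_file(out / "negative_control.txt")
        # per-class buffered exposures for the confounding scan
        for cls in config.scan_classes:
            sub = city.exposures[
                (city.exposures["wave"] == "baseline")
                & (city.exposures["land_use_class"] == cls)]
            table[f"exposure_{cls}_k"] = table["participant_id"].map(
                dict(zip(sub["participant_id"], sub["area_m2"]))) / 1_000.0
        scan = landuse_confounding_scan(table, specs["model2"],
                                        list(config.scan_classes))
        _write_csv(scan, out / "landuse_scan.csv", report, 6)
    except Exception:
        report.failed_stage = report.stages[-1]["stage"] \
            if report.stages else "init"
        _write_manifest(report, out)
        raise

    _write_manifest(report, out)
    return report


def _write_manifest(report: RunReport, out: Path) -> None:
    doc = {"seed": report.seed,
           "config": dataclasses.asdict(report.config),
           "stages": report.stages,
           "failed_stage": report.failed_stage,
           "files": report.manifest}
    (out / "manifest.json").write_text(json.dumps(doc, indent=2, default=str))
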