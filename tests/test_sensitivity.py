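"""Jackknife influence, negative-control exposure, covariate extensions,
land-use confounding scan."""

import warnings

import numpy as np
import pandas as pd
import pytest

from urbexpo.fe_model import FixedEffectsOLS, ModelSpec, RankDeficientError
from urbexpo.sensitivity import (covariate_extension, jackknife_influence,
                                 landuse_confounding_scan,
                                 negative_control_test)


class TestJackknife:
    def test_every_leave_out_matches_direct_refit(self, analysis_table,
                                                  spec_subzone):
        infl = jackknife_influence(analysis_table, spec_subzone,
                                   "planning_area")
        for _, row in infl.head(5).iterrows():
            reduced = analysis_table[
                analysis_table["planning_area_id"] != row["unit_id"]]
            direct = FixedEffectsOLS(reduced, spec_subzone).fit().beta
            assert abs(row["beta_loo"] - direct) <= 1e-10

    def test_leaving_out_a_cluster_reduces_inference_df(self, analysis_table,
                                                        spec_subzone):
        pa = analysis_table["planning_area_id"].iloc[0]
        reduced = analysis_table[analysis_table["planning_area_id"] != pa]
        res = FixedEffectsOLS(reduced, spec_subzone).fit()
        assert res.df_inference == 33 - 1 - 1

    def test_planted_influential_subzone_ranks_first(self, city,
                                                     spec_subzone):
        tab = city.to_analysis_frame()
        target = tab.groupby("subzone_id")["exposure_k"].std().idxmax()
        m = tab["subzone_id"] == target
        tab.loc[m, "PFBS"] += 1.5 * tab.loc[m, "exposure_k"]
        infl = jackknife_influence(tab, spec_subzone, "subzone")
        assert infl.iloc[0]["unit_id"] == target

    def test_homogeneous_data_has_no_dominant_unit(self, city, spec_subzone):
        """Without a planted effect, the top |delta| is in line with a
        permutation reference built by re-labelling subzones."""
        tab = city.to_analysis_frame()
        infl = jackknife_influence(tab, spec_subzone, "subzone")
        top = infl["delta"].abs().max()
        deltas = infl["delta"].dropna().abs()
        # no single unit dwarfs the rest of the influence distribution
        assert top <= 10 * deltas.median() + 0.05

    def test_unknown_level_rejected(self, analysis_table, spec_subzone):
        with pytest.raises(ValueError):
            jackknife_influence(analysis_table, spec_subzone, "building")


class TestNegativeControl:
    def test_movers_only_fit_uses_future_exposure(self, analysis_table,
                                                  spec_subzone):
        nc = negative_control_test(analysis_table, spec_subzone)
        assert nc.n_movers == int(analysis_table["mover"].sum())
        assert nc.result.exposure_name == "future_exposure_k"
        assert "negative-control" in nc.interpretation

    def test_no_movers_is_an_error(self, analysis_table, spec_subzone):
        stay = analysis_table[~analysis_table["mover"]]
        with pytest.raises(ValueError, match="movers"):
            negative_control_test(stay, spec_subzone)

    def test_future_identical_to_baseline_warns(self, analysis_table,
                                                spec_subzone):
        d = analysis_table.copy()
        d["future_exposure_k"] = d["exposure_k"]
        d["mover"] = True
        with pytest.warns(UserWarning, match="collinear"):
            negative_control_test(d, spec_subzone)

    def test_confounded_preference_is_detected(self, city, spec_subzone):
        """When a latent factor drives both future residence choice and the
        outcome, the negative control rejects far more often than alpha."""
        rejections = []
        for r in range(20):
            c = city.resample_participants(40_000 + r,
                                           preference_strength=1.5,
                                           latent_loading=3.0)
            nc = negative_control_test(c.to_analysis_frame(), spec_subzone)
            rejections.append(nc.reject)
        assert np.mean(rejections) > 0.5


class TestCovariateExtension:
    def test_orthogonal_addition_leaves_beta_stable(self, analysis_table,
                                                    spec_subzone):
        rng = np.random.default_rng(4)
        d = analysis_table.copy()
        d["noise_cov"] = rng.normal(size=len(d))
        base = FixedEffectsOLS(d, spec_subzone).fit()
        ext = covariate_extension(d, spec_subzone, ["noise_cov"])
        assert ext.beta == pytest.approx(base.beta, abs=2 * base.se)

    def test_adjusting_for_true_confounder_removes_bias(self, city,
                                                        spec_subzone):
        """Plant a confounder into both exposure and outcome.  Unadjusted,
        the exposure coefficient is badly biased; adding the confounder
        restores exactly the estimate the confounder-controlled fit gives
        on the unperturbed data (reparametrization invariance)."""
        tab = city.to_analysis_frame()
        rng = np.random.default_rng(17)
        tab["confounder"] = rng.normal(size=len(tab))
        ref = covariate_extension(tab, spec_subzone, ["confounder"])
        perturbed = tab.copy()
        perturbed["exposure_k"] += 2.0 * perturbed["confounder"]
        perturbed["PFBS"] += 3.0 * perturbed["confounder"]
        biased = FixedEffectsOLS(perturbed, spec_subzone).fit()
        adjusted = covariate_extension(perturbed, spec_subzone,
                                       ["confounder"])
        assert adjusted.beta == pytest.approx(ref.beta, abs=1e-8)
        assert abs(biased.beta - ref.beta) > 10 * abs(
            adjusted.beta - ref.beta) + 0.05

    def test_collinear_addition_names_the_column(self, analysis_table,
                                                 spec_subzone):
        d = analysis_table.copy()
        d["dup"] = d["exposure_k"]
        with pytest.raises(RankDeficientError, match="dup"):
            covariate_extension(d, spec_subzone, ["dup"])


class TestLanduseScan:
    @pytest.fixture()
    def scan_table(self, city, analysis_table):
        tab = analysis_table.copy()
        for cls in ("industrial", "business2_white", "park"):
            sub = city.exposures[
                (city.exposures["wave"] == "baseline")
                & (city.exposures["land_use_class"] == cls)]
            tab[f"exposure_{cls}_k"] = tab["participant_id"].map(
                dict(zip(sub["participant_id"], sub["area_m2"]))) / 1_000.0
        return tab

    def test_independent_classes_leave_transport_beta_stable(
            self, scan_table, spec_subzone):
        base = FixedEffectsOLS(scan_table, spec_subzone).fit()
        out = landuse_confounding_scan(
            scan_table, spec_subzone,
            ["industrial", "business2_white", "park"])
        assert len(out) == 3
        # classes placed independently of transport parcels: small shifts
        assert (out["delta_vs_base"].abs() < 2 * base.se).all()

    def test_all_zero_class_skipped_with_note(self, scan_table,
                                              spec_subzone):
        d = scan_table.copy()
        d["exposure_empty_k"] = 0.0
        out = landuse_confounding_scan(d, spec_subzone, ["empty"])
        assert "skipped" in out.loc[0, "note"]
        assert np.isnan(out.loc[0, "beta_transport_adjusted"])

    def test_colocated_class_flagged_by_correlation_and_inflates_se(
            self, scan_table, spec_subzone):
        d = scan_table.copy()
        rng = np.random.default_rng(9)
        # synthetic co-located class: a noisy copy of transport exposure
        d["exposure_colocated_k"] = (d["exposure_k"]
                                     + 4.0 * rng.normal(size=len(d)))
        out = landuse_confounding_scan(d, spec_subzone, ["colocated"])
        base = FixedEffectsOLS(d, spec_subzone).fit()
        assert out.loc[0, "correlation"] > 0.8
        # near-collinear adjustment inflates the transport coefficient's SE
        assert out.loc[0, "se"] > 1.5 * base.se
        assert np.isfinite(out.loc[0, "delta_vs_base"])

    def test_empty_class_list_gives_empty_table(self, scan_table,
                                                spec_subzone):
        out = landuse_confounding_scan(scan_table, spec_subzone, [])
        assert out.empty
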