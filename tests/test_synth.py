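"""Synthetic covariate fields, survey design, and presence generation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from racbrt import (
    CovariateSpec,
    ResponseSpec,
    build_weights,
    default_covariate_specs,
    default_response_spec,
    design_survey,
    full_coverage_design,
    generate_grid,
    morans_i,
    portugal_like_mask,
    simulate_covariates,
    simulate_presence,
    survey_effort_km,
)
from racbrt.registry import Collinearity


@pytest.fixture(scope="module")
def grid20():
    return generate_grid(20, 20, 5.0)


class TestSimulateCovariates:
    def test_sample_mean_matches_spec_over_seeds(self, grid20):
        spec = CovariateSpec("v", "H1_landcover", 12.7, (0.0, 78.4), 0.0)
        for seed in range(1, 11):
            cov = simulate_covariates(grid20, [spec], seed=seed)
            assert cov["v"].mean() == pytest.approx(12.7, rel=0.05)

    def test_exact_collinear_copy_has_unit_correlation(self, grid20):
        specs = [
            CovariateSpec("src", "H1_landcover", 10.0, (0.0, 50.0), 2.0),
            CovariateSpec(
                "copy", "H1_landcover", 10.0, (0.0, 50.0), 2.0,
                collinear_with=Collinearity(("src",), (1.0,)),
            ),
        ]
        cov = simulate_covariates(grid20, specs, seed=3)
        assert cov["src"].corr(cov["copy"]) == pytest.approx(1.0)

    def test_values_stay_inside_printed_range(self, grid20):
        cov = simulate_covariates(grid20, default_covariate_specs(), seed=9)
        assert cov["Ann_Prec"].between(526.63, 1614.83).all()
        for spec in default_covariate_specs():
            lo, hi = spec.range
            assert cov[spec.name].between(lo, hi).all(), spec.name

    def test_range_bound_saturation_under_five_percent(self, grid20):
        # the marginal transform must not pile mass onto the bounds
        cov = simulate_covariates(grid20, default_covariate_specs(), seed=4)
        for spec in default_covariate_specs():
            if spec.binary or spec.collinear_with is not None:
                continue
            lo, hi = spec.range
            if spec.mean - lo <= 0.01 * (hi - lo):
                continue  # zero-inflated by design (e.g. Exotic cover)
            at_bounds = ((cov[spec.name] <= lo) | (cov[spec.name] >= hi)).mean()
            assert at_bounds <= 0.05, spec.name

    def test_unknown_collinear_source_rejected(self, grid20):
        bad = CovariateSpec(
            "x", "H1_landcover", 1.0, (0.0, 2.0),
            collinear_with=Collinearity(("ghost",), (1.0,)),
        )
        with pytest.raises(KeyError, match="ghost"):
            simulate_covariates(grid20, [bad], seed=0)

    def test_binary_spec_yields_balanced_indicator(self, grid20):
        spec = CovariateSpec("hunt", "H2_disturbance", 0.5, (0, 1), 2.0, binary=True)
        cov = simulate_covariates(grid20, [spec], seed=5)
        assert set(cov["hunt"].unique()) == {0.0, 1.0}
        assert cov["hunt"].mean() == pytest.approx(0.5, abs=0.01)

    def test_bitwise_reproducibility(self, grid20):
        a = simulate_covariates(grid20, seed=7)
        b = simulate_covariates(grid20, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestSurveyDesign:
    def test_study_design_dimensions(self):
        # 136 blocks x 2 quadrants x 5 transects of 0.5 km
        g10 = generate_grid(33, 30, 10.0, portugal_like_mask())
        design, g5 = design_survey(g10, seed=1, n_blocks=136)
        assert len(design.selected_10km_cells) == 136
        assert len(design.sampled_cell_ids) == 272
        assert design.total_effort_km == pytest.approx(272 * 5 * 0.5)

    def test_quadrants_distinct_and_within_block(self):
        g10 = generate_grid(10, 10, 10.0)
        design, g5 = design_survey(g10, seed=2)
        for block, (a, b) in design.subcells_5km.items():
            assert a != b
            br, bc = g10.row_col(block)
            for cid in (a, b):
                r, c = g5.row_col(cid)
                assert r // 2 == br and c // 2 == bc

    def test_effort_arithmetic_from_printed_counts(self):
        # the field campaign's own numbers: 1315 transects of 500 m
        assert survey_effort_km(1315, 0.5) == pytest.approx(657.5)

    def test_requesting_more_blocks_than_pattern_rejected(self):
        g10 = generate_grid(5, 5, 10.0)
        with pytest.raises(ValueError):
            design_survey(g10, n_blocks=100)


class TestSimulatePresence:
    def test_perfect_detection_recovers_latent_occupancy(self, grid20):
        cov = simulate_covariates(grid20, seed=1)
        resp = ResponseSpec(
            effects={}, intercept=0.0, spatial_noise_sd=1.0,
            detection_prob_per_transect=1.0,
        )
        design = full_coverage_design(grid20)
        pres, _ = simulate_presence(grid20, cov, resp, design, seed=2)
        sampled = pres[pres["sampled"]]
        assert (sampled["presence"] == sampled["occupied"]).all()

    def test_prevalence_hits_35_percent_with_null_effects(self, grid20):
        # flat response at logit(0.35), no noise, perfect detection:
        # the observed prevalence is a plain binomial draw around 0.35
        cov = simulate_covariates(grid20, seed=1)
        design = full_coverage_design(grid20)
        resp = ResponseSpec(
            effects={}, intercept=float(logit(0.35)), spatial_noise_sd=0.0,
            detection_prob_per_transect=1.0,
        )
        prevs = []
        for seed in range(1, 21):
            pres, info = simulate_presence(grid20, cov, resp, design, seed=seed)
            prevs.append(info["observed_prevalence"])
        assert np.mean(prevs) == pytest.approx(0.35, abs=0.02)

    def test_default_calibration_targets_35_percent(self):
        g10 = generate_grid(33, 30, 10.0, portugal_like_mask())
        design, g5 = design_survey(g10, seed=3, n_blocks=136)
        cov = simulate_covariates(g5, seed=3)
        prevs = []
        for seed in range(1, 9):
            _, info = simulate_presence(g5, cov, default_response_spec(), design, seed=seed)
            prevs.append(info["observed_prevalence"])
        assert np.mean(prevs) == pytest.approx(0.35, abs=0.03)

    def test_missing_covariate_for_effect_rejected(self, grid20):
        cov = simulate_covariates(grid20, seed=1)[["row", "col", "x_km", "y_km", "H"]]
        with pytest.raises(KeyError):
            simulate_presence(
                grid20, cov, default_response_spec(), full_coverage_design(grid20), seed=0
            )

    def test_presence_is_spatially_autocorrelated(self, grid20):
        # latent noise with positive range must leave a significantly
        # positive Moran's I on observed presence in nearly all runs
        cov = simulate_covariates(grid20, seed=2)
        design = full_coverage_design(grid20)
        w = build_weights(grid20)
        resp = default_response_spec()
        hits = 0
        for seed in range(50):
            pres, _ = simulate_presence(grid20, cov, resp, design, seed=seed)
            obs = pres.loc[pres["sampled"], "presence"]
            res = morans_i(obs, w, alternative="greater")
            hits += (res.I > 0) and (res.p_value < 0.05)
        assert hits >= 45

    def test_bitwise_reproducibility(self, grid20):
        cov = simulate_covariates(grid20, seed=2)
        design = full_coverage_design(grid20)
        a, ia = simulate_presence(grid20, cov, default_response_spec(), design, seed=9)
        b, ib = simulate_presence(grid20, cov, default_response_spec(), design, seed=9)
        pd.testing.assert_frame_equal(a, b)
        assert ia == ib
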