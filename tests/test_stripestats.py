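"""ROI logic, deconfounding, stripe statistics, permutation machinery."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import v2qstripes as v2
from v2qstripes.cohort import CohortConfig, generate_cohort, paper_effect_mode
from v2qstripes.stripestats import (
    residualize,
    define_stripe_rois,
    stripe_statistic,
    group_statistic,
    corrected_pvalue,
    coverage_summary,
    reliability_correlation,
    prepare_hemisphere_maps,
    permutation_test,
    threshold_sweep,
    z_threshold_pvalue,
    significance_stars,
)
from v2qstripes.patch import gaussian_random_field


class TestResidualize:
    def test_exact_linear_curvature_dependence_removed(self, small_patch):
        rng = np.random.default_rng(0)
        curv = rng.standard_normal(small_patch.n_vertices)
        qmap = 0.6 + 0.04 * curv
        resid = residualize(qmap, curv, small_patch.v2_mask)
        assert np.allclose(resid, 0.0, atol=1e-12)

    def test_zero_curvature_reduces_to_mean_subtraction(self, small_patch):
        rng = np.random.default_rng(1)
        qmap = rng.normal(0.58, 0.05, small_patch.n_vertices)
        resid = residualize(qmap, np.zeros_like(qmap), small_patch.v2_mask)
        assert np.allclose(resid, qmap - qmap.mean())

    def test_injected_coupling_decorrelated(self, small_patch):
        """Synthetic coupling of 0.02 per unit curvature: the residual map's
        correlation with curvature drops below 0.01."""
        rng = np.random.default_rng(2)
        curv = gaussian_random_field(small_patch.grid_shape, 0.8, 3.0, rng, sd=0.15)
        qmap = 0.58 + 0.02 * curv + rng.normal(0, 0.005, small_patch.n_vertices)
        resid = residualize(qmap, curv, small_patch.v2_mask)
        assert abs(np.corrcoef(resid, curv)[0, 1]) < 0.01

    def test_empty_mask_raises(self, small_patch):
        with pytest.raises(ValueError):
            residualize(np.ones(small_patch.n_vertices), small_patch.curvature,
                        np.zeros(small_patch.n_vertices, dtype=bool))


class TestROIDefinition:
    def test_spec_of_overlap_discard_on_toy_maps(self):
        z_color = np.array([3.0, 1.0, 3.0, 0.0, 2.0])
        z_disp = np.array([0.0, 3.0, 3.0, 1.0, 0.0])
        v2m = np.ones(5, dtype=bool)
        roi = define_stripe_rois(z_color, z_disp, v2m, 1.96)
        assert np.array_equal(np.flatnonzero(roi.thin_mask), [0, 4])
        assert np.array_equal(np.flatnonzero(roi.thick_mask), [1])
        assert np.array_equal(np.flatnonzero(roi.rest_minus_thick), [0, 3, 4])
        assert np.array_equal(np.flatnonzero(roi.rest_minus_thin), [1, 3])

    def test_threshold_above_max_flags_empty(self):
        roi = define_stripe_rois(np.array([1.0, 2.0]), np.array([0.5, 0.1]),
                                 np.ones(2, bool), 10.0)
        assert roi.empty_thin and roi.empty_thick

    def test_partition_of_suprathreshold_vertices(self):
        """thin, thick, and the discarded overlap partition the
        supra-threshold set (brute-force enumeration on random maps)."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            zc, zd = rng.standard_normal((2, 200))
            v2m = rng.random(200) < 0.8
            thr = rng.uniform(0, 2)
            roi = define_stripe_rois(zc, zd, v2m, thr)
            supra = ((zc >= thr) | (zd >= thr)) & v2m
            overlap = (zc >= thr) & (zd >= thr) & v2m
            union = roi.thin_mask | roi.thick_mask | overlap
            assert not (roi.thin_mask & roi.thick_mask).any()
            assert np.array_equal(union, supra)

    def test_negative_threshold_raises(self):
        with pytest.raises(ValueError):
            define_stripe_rois(np.ones(3), np.ones(3), np.ones(3, bool), -0.5)


class TestStripeStatistic:
    def test_constant_residuals_give_zero(self):
        roi = define_stripe_rois(np.array([3.0, 0.0, 0.0]), np.array([0.0, 3.0, 0.0]),
                                 np.ones(3, bool), 1.0)
        d_thin, d_thick = stripe_statistic(np.zeros(3), roi, np.ones(3))
        assert d_thin == 0.0 and d_thick == 0.0

    def test_hand_computed_toy_example(self):
        """thin = {v0}, rest-minus-thick = {v0, v3, v4} on values
        [-1, 0, 0, 0, 0]: d_thin = -1 - (-1/3) = -2/3."""
        v2m = np.ones(5, bool)
        roi = v2.ROISet(
            threshold=0.0,
            thin_mask=np.array([1, 0, 0, 0, 0], bool),
            thick_mask=np.array([0, 1, 1, 0, 0], bool),
            rest_minus_thin=np.array([0, 1, 1, 1, 1], bool),
            rest_minus_thick=np.array([1, 0, 0, 1, 1], bool),
        )
        d_thin, _ = stripe_statistic(np.array([-1.0, 0, 0, 0, 0]), roi, np.ones(5))
        assert d_thin == pytest.approx(-2.0 / 3.0)

    def test_invariance_to_offset_and_curvature_confound(self, small_patch):
        """The full residualize + statistic chain is unchanged by adding a
        constant or any linear function of curvature to the qMRI map."""
        rng = np.random.default_rng(4)
        curv = gaussian_random_field(small_patch.grid_shape, 0.8, 3.0, rng, sd=0.2)
        patched = small_patch
        qmap = rng.normal(0.58, 0.02, patched.n_vertices)
        zc, zd = rng.standard_normal((2, patched.n_vertices))
        roi = define_stripe_rois(zc, zd, patched.v2_mask, 1.0)
        base = stripe_statistic(residualize(qmap, curv, patched.v2_mask), roi, patched.vertex_area)
        confounded = qmap + 0.3 + 0.07 * curv
        alt = stripe_statistic(residualize(confounded, curv, patched.v2_mask), roi, patched.vertex_area)
        assert base == pytest.approx(alt, abs=1e-12)

    def test_empty_roi_gives_nan(self):
        roi = define_stripe_rois(np.zeros(3), np.zeros(3), np.ones(3, bool), 1.0)
        d_thin, _ = stripe_statistic(np.zeros(3), roi, np.ones(3))
        assert np.isnan(d_thin)


class TestGroupStatistic:
    def test_mean_and_order_invariance(self):
        assert group_statistic([-0.004, -0.006]) == pytest.approx(-0.005)
        assert group_statistic([1.0, 2.0, 3.0]) == group_statistic([3.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            group_statistic([])


class TestCorrectedPvalue:
    def test_frozen_arithmetic_examples(self):
        # k=100, n=10000: sigma = sqrt(99), p = (100 + 3 sqrt(99))/10000
        assert corrected_pvalue(100, 10000) == pytest.approx(0.012985, abs=1e-6)
        # k=0: p_hat = 1/n keeps the guard positive
        assert corrected_pvalue(0, 10000) == pytest.approx(2.99985e-4, rel=1e-4)
        assert corrected_pvalue(10000, 10000) == 1.0

    def test_median_observed_gives_half(self):
        assert corrected_pvalue(5000, 10000) == pytest.approx(0.5, abs=0.02)

    @given(st.integers(0, 500), st.integers(2, 500))
    def test_bounds_and_conservativeness(self, k, n):
        k = min(k, n)
        p = corrected_pvalue(k, n)
        assert 0.0 < p <= 1.0
        assert p >= k / n

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            corrected_pvalue(5, 0)
        with pytest.raises(ValueError):
            corrected_pvalue(7, 5)

    def test_threshold_pvalue_convention(self):
        assert z_threshold_pvalue(1.96) <= 0.05
        assert significance_stars(0.02) == "*"
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.2) == ""


class TestCoverage:
    def test_counting_toy_example(self):
        v2m = np.ones(5, bool)
        roi = v2.ROISet(0.0,
                        thin_mask=np.array([1, 1, 0, 0, 0], bool),
                        thick_mask=np.array([0, 0, 1, 0, 0], bool),
                        rest_minus_thin=~np.array([1, 1, 0, 0, 0], bool),
                        rest_minus_thick=~np.array([0, 0, 1, 0, 0], bool))
        thin, thick, pale = coverage_summary(roi, v2m, np.ones(5))
        assert (thin, thick, pale) == (40.0, 20.0, 40.0)

    def test_above_threshold_everything_pale(self):
        roi = define_stripe_rois(np.zeros(4), np.zeros(4), np.ones(4, bool), 5.0)
        thin, thick, pale = coverage_summary(roi, np.ones(4, bool), np.ones(4))
        assert pale == 100.0


@pytest.fixture(scope="module")
def effect_hemis(small_surrogate_gen):
    cfg = paper_effect_mode(CohortConfig(
        n_subjects=2, hemispheres_per_subject=2,
        patch_width_mm=16, patch_height_mm=8, spacing_mm=0.8,
        seed=21,
    ))
    # strengthen the effect so the small desk cohort has power
    from dataclasses import replace
    cfg = replace(cfg, delta_thin=cfg.delta_thin * 6, delta_thick=cfg.delta_thick * 6)
    cohort = generate_cohort(cfg)
    return prepare_hemisphere_maps(cohort, surrogate_gen=small_surrogate_gen)


class TestPermutationInference:
    def test_detects_strong_effect(self, effect_hemis):
        res = permutation_test(effect_hemis, threshold=1.0, n=200, seed=0)
        assert res["thick"].observed < 0
        assert res["thick"].p_corrected < 0.05
        assert res["thin"].p_corrected < 0.1
        assert res["thick"].k <= res["thick"].n

    def test_null_values_reproducible(self, effect_hemis):
        a = permutation_test(effect_hemis, threshold=1.0, n=150, seed=3)
        b = permutation_test(effect_hemis, threshold=1.0, n=150, seed=3)
        assert np.array_equal(a["thin"].null_values, b["thin"].null_values)
        assert a["thin"].p_corrected == b["thin"].p_corrected

    def test_small_n_rejected(self, effect_hemis):
        with pytest.raises(ValueError):
            permutation_test(effect_hemis, threshold=1.0, n=50)

    def test_threshold_sweep_shape_and_monotone_supra_sets(self, effect_hemis):
        sweep = threshold_sweep(effect_hemis, n=100, seed=1)
        assert len(sweep) == 10
        # raw supra-threshold sets shrink monotonically with the threshold
        # (the overlap-discarded ROIs need not: discarding shrinks too)
        assert np.all(np.diff(sweep["n_supra_color"]) <= 0)
        assert np.all(np.diff(sweep["n_supra_disparity"]) <= 0)
        assert np.all(sweep["n_thin_vertices"] <= sweep["n_supra_color"])
        assert set(sweep.columns) >= {"threshold", "d_thin", "d_thick", "p_thin", "p_thick"}


class TestPoolingVariants:
    def test_vertex_pooling_matches_hemisphere_pooling_on_identical_hemis(self, effect_hemis):
        """With identical per-hemisphere geometry and maps duplicated, vertex
        pooling of one hemisphere equals its hemisphere statistic."""
        from v2qstripes.stripestats import observed_pooled_statistics

        one = effect_hemis[:1]
        a = observed_pooled_statistics(one, 1.0, pooling="hemisphere")
        b = observed_pooled_statistics(one, 1.0, pooling="vertex")
        assert a == pytest.approx(b)
        # across hemispheres the two poolings agree closely on a balanced cohort
        h_all = observed_pooled_statistics(effect_hemis, 1.0, pooling="hemisphere")
        v_all = observed_pooled_statistics(effect_hemis, 1.0, pooling="vertex")
        assert h_all[1] == pytest.approx(v_all[1], rel=0.2)
        with pytest.raises(ValueError):
            observed_pooled_statistics(one, 1.0, pooling="bogus")


class TestReliability:
    def test_identical_maps_correlate_perfectly(self, small_patch, small_surrogate_gen):
        rng = np.random.default_rng(0)
        m = gaussian_random_field(small_patch.grid_shape, 0.8, 2.0, rng)
        res = reliability_correlation(m, m, small_patch.v2_mask,
                                      surrogate_gen=small_surrogate_gen, n=150, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_corrected < 0.05

    def test_rank_reversal_gives_minus_one(self, small_patch, small_surrogate_gen):
        rng = np.random.default_rng(1)
        m = rng.standard_normal(small_patch.n_vertices)
        res = reliability_correlation(m, -m, small_patch.v2_mask,
                                      surrogate_gen=small_surrogate_gen, n=150, seed=0)
        assert res.r == pytest.approx(-1.0)
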