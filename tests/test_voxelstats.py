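"""GLM, TFCE and parcellation against hand calculations and naive oracles."""

import numpy as np
import pytest
from scipy import stats

import regiontx as rt
from regiontx.voxelstats import DesignError, StatMap


def _full_mask(shape=(6, 6, 6)):
    return np.ones(shape, dtype=bool)


class TestSmoothing:
    def test_constant_volume_unchanged(self, rng):
        mask = rng.random((8, 8, 8)) > 0.3
        out = rt.smooth_gaussian(np.full((8, 8, 8), 3.5), mask, fwhm_mm=3.0)
        assert np.allclose(out[mask], 3.5)

    def test_zero_fwhm_is_identity(self, rng):
        vol = rng.normal(size=(6, 6, 6))
        mask = _full_mask()
        assert np.array_equal(rt.smooth_gaussian(vol, mask, 0.0), vol)

    def test_impulse_mass_conserved(self):
        vol = np.zeros((21, 21, 21))
        vol[10, 10, 10] = 1.0
        out = rt.smooth_gaussian(vol, np.ones_like(vol, bool), fwhm_mm=3.0)
        assert abs(out.sum() - 1.0) < 1e-6

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            rt.smooth_gaussian(np.zeros((4, 4, 4)), _full_mask((4, 4, 4)), -1.0)


class TestGLM:
    def test_hand_computed_two_sample_case(self):
        # groups A={0,1}, B={1,2} at a single voxel: t = 1.4142 with df=2
        data = np.array([0.0, 1.0, 1.0, 2.0]).reshape(4, 1, 1, 1)
        cohort = rt.VoxelCohort(
            data, np.array([0, 0, 1, 1]), np.zeros((4, 0)), np.ones((1, 1, 1), bool)
        )
        t = rt.fit_glm_tmap(cohort).values[0, 0, 0]
        assert abs(t - 1.4142) < 1e-4

    def test_matches_two_sample_t_without_covariates(self, rng):
        data = rng.normal(size=(24, 10, 10, 10))
        group = np.repeat([0, 1], 12)
        cohort = rt.VoxelCohort(data, group, np.zeros((24, 0)), _full_mask((10, 10, 10)))
        mine = rt.fit_glm_tmap(cohort).values.ravel()
        ref = stats.ttest_ind(
            data[group == 1].reshape(12, -1), data[group == 0].reshape(12, -1)
        ).statistic
        assert np.max(np.abs(mine - ref)) < 1e-10

    def test_zero_slope_covariates_match_plain_t(self, rng):
        data = rng.normal(size=(20, 5, 5, 5))
        group = np.repeat([0, 1], 10)
        cov = rng.normal(size=(20, 2))
        cohort = rt.VoxelCohort(data, group, cov, _full_mask((5, 5, 5)))
        adj = rt.fit_glm_tmap(cohort).values
        # same contrast via explicit OLS residualisation per voxel
        X = np.column_stack([np.ones(20), group, cov])
        beta = np.linalg.lstsq(X, data.reshape(20, -1), rcond=None)[0]
        resid = data.reshape(20, -1) - X @ beta
        sigma2 = (resid**2).sum(axis=0) / (20 - 4)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert np.max(np.abs(adj.ravel() - beta[1] / se)) < 1e-10

    def test_collinear_design_rejected(self):
        data = np.random.default_rng(0).normal(size=(10, 3, 3, 3))
        group = np.repeat([0, 1], 5)
        cohort = rt.VoxelCohort(
            data, group, group.astype(float)[:, None], _full_mask((3, 3, 3))
        )
        with pytest.raises(DesignError):
            rt.fit_glm_tmap(cohort)

    def test_negating_volumes_negates_t(self, rng):
        data = rng.normal(size=(16, 4, 4, 4))
        group = np.repeat([0, 1], 8)
        cov = rng.normal(size=(16, 1))
        mask = _full_mask((4, 4, 4))
        t1 = rt.fit_glm_tmap(rt.VoxelCohort(data, group, cov, mask)).values
        t2 = rt.fit_glm_tmap(rt.VoxelCohort(-data, group, cov, mask)).values
        assert np.array_equal(t1, -t2)


class TestTFCE:
    def test_single_voxel_analytic_limit(self):
        # isolated voxel of height 1: TFCE -> integral of h^2 over [0,1] = 1/3
        vol = np.zeros((5, 5, 5))
        vol[2, 2, 2] = 1.0
        out = rt.tfce_enhance(
            StatMap(vol, "t", _full_mask((5, 5, 5))), rt.TFCEParams(), dh=0.001
        )
        assert abs(out.values[2, 2, 2] - 1 / 3) / (1 / 3) < 0.005

    def test_zero_map_stays_zero(self):
        out = rt.tfce_enhance(
            StatMap(np.zeros((4, 4, 4)), "t", _full_mask((4, 4, 4))), rt.TFCEParams()
        )
        assert np.array_equal(out.values, np.zeros((4, 4, 4)))

    def test_matches_naive_oracle_exactly(self, rng, tfce_naive):
        """Vectorised TFCE equals per-component loop summation at equal step."""
        for _ in range(5):
            t = rng.normal(size=(6, 6, 6))
            mask = _full_mask()
            dh = np.abs(t).max() / 50
            mine = rt.tfce_enhance(
                StatMap(t, "t", mask), rt.TFCEParams(n_steps=50), dh=dh
            ).values
            oracle = tfce_naive(t, mask, 0.5, 2.0, dh, 26)
            assert np.max(np.abs(mine - oracle)) < 1e-10 * np.abs(oracle).max()

    def test_scaling_law(self, rng):
        """With dh scaled alongside the map, TFCE scales as lambda^(H+1)."""
        t = rng.normal(size=(6, 6, 6))
        mask = _full_mask()
        params = rt.TFCEParams()
        base = rt.tfce_enhance(StatMap(t, "t", mask), params).values
        lam = 2.5
        scaled = rt.tfce_enhance(StatMap(lam * t, "t", mask), params).values
        assert np.allclose(scaled, lam ** (params.H + 1) * base, rtol=1e-10)

    def test_two_sided_antisymmetry(self, rng):
        t = rng.normal(size=(6, 6, 6))
        mask = _full_mask()
        dh = np.abs(t).max() / 100
        a = rt.tfce_enhance(StatMap(t, "t", mask), rt.TFCEParams(), dh=dh).values
        b = rt.tfce_enhance(StatMap(-t, "t", mask), rt.TFCEParams(), dh=dh).values
        assert np.array_equal(a, -b)

    def test_connectivity_changes_components(self):
        # two diagonal voxels: one component under 26-connectivity, two under 6
        vol = np.zeros((4, 4, 4))
        vol[1, 1, 1] = vol[2, 2, 2] = 1.0
        mask = _full_mask((4, 4, 4))
        v26 = rt.tfce_enhance(StatMap(vol, "t", mask), rt.TFCEParams(connectivity=26)).values
        v6 = rt.tfce_enhance(StatMap(vol, "t", mask), rt.TFCEParams(connectivity=6)).values
        assert v26[1, 1, 1] > v6[1, 1, 1]


class TestPermutationFWE:
    def test_p_floor_and_determinism(self, small_atlas):
        cohort, _ = rt.gen_cohort(small_atlas, 5, 0.0, set(), seed=0)
        params = rt.TFCEParams(n_perm=30, seed=4)
        _, _, p1 = rt.permutation_fwe(cohort, params)
        _, _, p2 = rt.permutation_fwe(cohort, params)
        assert np.array_equal(p1.values, p2.values)
        assert p1.values[cohort.mask].min() >= 1 / 31 - 1e-12

    def test_planted_blob_detected(self):
        atlas = rt.gen_atlas((12, 12, 12), 8, seed=2)
        cohort, truth = rt.gen_cohort(atlas, 20, 3.0, {1}, seed=3)
        _, _, p = rt.permutation_fwe(cohort, rt.TFCEParams(n_perm=200, seed=5))
        assert (p.values[truth.effect_mask] < 0.05).all()


class TestParcellate:
    def test_constant_map(self, small_atlas):
        stat = StatMap(np.full((12, 12, 12), 2.5), "t", small_atlas.mask)
        ph = rt.parcellate(stat, small_atlas)
        assert np.allclose(ph.values, 2.5)

    def test_matches_naive_per_label_mean(self, small_atlas, rng):
        values = rng.normal(size=(12, 12, 12))
        stat = StatMap(values, "t", small_atlas.mask)
        ph = rt.parcellate(stat, small_atlas)
        for rid, v in zip(ph.region_ids, ph.values):
            assert abs(v - values[small_atlas.labels == rid].mean()) < 1e-12

    def test_empty_region_flagged_missing(self, small_atlas, rng):
        mask = small_atlas.mask & (small_atlas.labels != 3)
        stat = StatMap(rng.normal(size=(12, 12, 12)), "t", mask)
        with pytest.warns(UserWarning, match="no in-mask voxels"):
            ph = rt.parcellate(stat, small_atlas)
        assert np.isnan(ph.values[list(small_atlas.region_ids).index(3)])
        assert np.isfinite(np.delete(ph.values, list(small_atlas.region_ids).index(3))).all()
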