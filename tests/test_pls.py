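"""PLS fit, weight alignment and null-calibrated gene ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import regiontx as rt


class TestZScore:
    def test_columns_standardised(self, rng):
        df = pd.DataFrame(rng.normal(5, 2, size=(40, 6)))
        z = rt.zscore_columns(df)
        assert np.allclose(z.mean(), 0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1, atol=1e-12)

    def test_idempotent(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 4)))
        z1 = rt.zscore_columns(df)
        z2 = rt.zscore_columns(z1)
        assert np.allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)

    def test_constant_column_dropped_with_warning(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        with pytest.warns(UserWarning, match="zero-variance"):
            z = rt.zscore_columns(df)
        assert list(z.columns) == ["a"]

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            rt.zscore_vector(np.ones(10))


class TestPLSFit:
    def test_component1_weights_closed_form(self, rng):
        """For univariate y, w1 is the normalised X'y (gene-phenotype covariances)."""
        X = rng.normal(size=(30, 200))
        y = rng.normal(size=30)
        model = rt.plsr_fit(X, y, 3)
        Xc = X - X.mean(axis=0)
        ref = Xc.T @ (y - y.mean())
        ref /= np.linalg.norm(ref)
        assert abs(abs(model.weights[:, 0] @ ref) - 1) < 1e-10

    def test_single_predictor_equal_to_response(self, rng):
        y = rng.normal(size=20)
        model = rt.plsr_fit(y[:, None], y, 1)
        assert model.explained_variance_y[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_sklearn_nipals(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(25, 60))
        y = rng.normal(size=25)
        model = rt.plsr_fit(X, y, 4)
        ref = sklearn.PLSRegression(n_components=4, scale=False).fit(X, y[:, None])
        for k in range(4):
            assert abs(abs(model.weights[:, k] @ ref.x_weights_[:, k]) - 1) < 1e-8

    def test_scores_orthogonal(self, rng):
        X = rng.normal(size=(30, 80))
        model = rt.plsr_fit(X, rng.normal(size=30), 5)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))

    def test_explained_variance_invariances(self, rng):
        X = rng.normal(size=(25, 40))
        y = rng.normal(size=25)
        ev = rt.plsr_fit(X, y, 3).explained_variance_y
        perm = rng.permutation(40)
        ev_perm = rt.plsr_fit(X[:, perm], y, 3).explained_variance_y
        flip = np.where(rng.random(40) < 0.5, -1.0, 1.0)
        ev_flip = rt.plsr_fit(X * flip, y, 3).explained_variance_y
        assert np.allclose(ev, ev_perm, atol=1e-10)
        assert np.allclose(ev, ev_flip, atol=1e-10)
        assert (ev >= -1e-12).all() and ev.sum() <= 1 + 1e-12

    def test_component_range_enforced(self, rng):
        X = rng.normal(size=(10, 5))
        with pytest.raises(ValueError):
            rt.plsr_fit(X, rng.normal(size=10), 10)
        with pytest.raises(ValueError):
            rt.plsr_fit(X, rng.normal(size=10), 0)


class TestAlignment:
    def test_sign_convention(self, rng):
        X = rng.normal(size=(30, 50))
        y = rng.normal(size=30)
        model = rt.plsr_fit(X, y, 3)
        for k in range(1, 4):
            w = rt.align_weights(model, y, k)
            r = np.corrcoef(model.scores[:, k - 1], y)[0, 1]
            expected = np.sign(r) * model.weights[:, k - 1]
            assert np.array_equal(w, expected)

    def test_component1_never_flips(self, rng):
        # NIPALS component-1 scores always correlate positively with y
        X = rng.normal(size=(20, 30))
        y = rng.normal(size=20)
        model = rt.plsr_fit(X, y, 1)
        assert model.score_phenotype_corr[0] > 0
        assert np.array_equal(rt.align_weights(model, y, 1), model.weights[:, 0])

    def test_top_weight_gene_positively_coupled(self, recovery_study):
        s = recovery_study
        model = rt.plsr_fit(s["X"], s["y"], 1)
        w = rt.align_weights(model, s["y"], 1)
        top_gene = s["X"].columns[np.argmax(w)]
        r = np.corrcoef(s["X"][top_gene], s["y"])[0, 1]
        assert r > 0
        assert top_gene in {g for g, rho in s["coupling"].items() if rho > 0}


class TestGeneZ:
    def test_ranking_deterministic(self, recovery_study):
        s = recovery_study
        r2 = rt.gene_z_scores(s["X"], s["y"], s["surrogates"], k=1)
        pd.testing.assert_frame_equal(s["ranking"], r2)

    def test_planted_genes_in_extreme_z(self, recovery_study):
        s = recovery_study
        absz = s["ranking"]["z"].abs().sort_values(ascending=False)
        top = set(absz.index[:100])
        assert len(top & set(s["coupling"])) >= 90

    def test_uncoupled_z_sd_calibrated(self, recovery_study):
        s = recovery_study
        null_z = s["ranking"]["z"][~s["ranking"].index.isin(s["coupling"])]
        assert 0.5 <= null_z.std() <= 2.0

    def test_ranking_stable_across_ensembles(self, recovery_study):
        s = recovery_study
        ens2 = rt.generate_surrogates(
            s["phenotype"].values, s["atlas"].centroids, n_null=200, seed=999
        )
        r2 = rt.gene_z_scores(s["X"], s["y"], ens2, k=1)
        joined = s["ranking"][["z"]].join(r2[["z"]], rsuffix="_b")
        rho = spearmanr(joined["z"], joined["z_b"]).statistic
        assert rho > 0.9

    def test_zero_null_sd_genes_excluded(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 10)), columns=[f"g{i}" for i in range(10)])
        y = rng.normal(size=20)
        # two identical surrogate maps -> zero null SD everywhere
        m = rng.normal(size=20)
        ens = rt.SurrogateEnsemble(np.stack([m, m]), 0, np.zeros(2))
        ranking = rt.gene_z_scores(X, y, ens, k=1)
        assert len(ranking) == 0

    def test_mismatched_regions_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 5)))
        ens = rt.SurrogateEnsemble(rng.normal(size=(3, 19)), 0, np.zeros(3))
        with pytest.raises(ValueError):
            rt.gene_z_scores(X, rng.normal(size=20), ens)


class TestValidation:
    def test_recovery_slopes_signed_correctly(self, recovery_study):
        s = recovery_study
        val = rt.validate_ranking(s["expression"], s["phenotype"].values, s["ranking"], 5)
        assert (val.loc[val["end"] == "top", "slope"] > 0).all()
        assert (val.loc[val["end"] == "bottom", "slope"] < 0).all()

    def test_gene_identical_to_phenotype(self, rng):
        y = rng.normal(size=30)
        X = pd.DataFrame({"same": y, "noise": rng.normal(size=30)})
        ranking = pd.DataFrame({"z": [5.0, 0.1]}, index=pd.Index(["same", "noise"], name="gene"))
        val = rt.validate_ranking(X, y, ranking, 1)
        assert val.loc["same", "r"] == pytest.approx(1.0)

    def test_oversized_k_top_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 6)))
        ranking = pd.DataFrame({"z": np.arange(6.0)}, index=X.columns)
        with pytest.raises(ValueError):
            rt.validate_ranking(X, rng.normal(size=10), ranking, 4)
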