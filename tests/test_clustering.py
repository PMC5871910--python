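"""Marker scaling, hierarchical/spectral clustering, per-cluster statistics."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

import scwb
from scwb.clustering import (cluster_composition, default_epsilon, hcluster,
                             per_cluster_stats, scale_markers,
                             spectral_spectrum)
from scwb.synthetic import simulate_marker_mixture


class TestScaleMarkers:
    def test_simple_column(self):
        out = scale_markers(pd.DataFrame({"m": [1.0, 2.0, 3.0]}))
        assert np.allclose(out["m"], [-1, 0, 1])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.lognormal(10, 1, size=(50, 4)),
                         columns=list("abcd"))
        out = scale_markers(X)
        assert np.allclose(out.mean(), 0, atol=1e-12)
        assert np.allclose(out.std(ddof=1), 1, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        once = scale_markers(X)
        pd.testing.assert_frame_equal(scale_markers(once), once)

    def test_constant_column_named_in_error(self):
        X = pd.DataFrame({"good": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            scale_markers(X)


class TestHierarchical:
    def test_two_separated_clouds(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (20, 3)),
                       rng.normal(100, 1, (20, 3))])
        truth = np.array([0] * 20 + [1] * 20)
        res = hcluster(X, 2)
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_k_equals_n_singletons(self):
        X = np.arange(12, dtype=float).reshape(6, 2)
        res = hcluster(X, 6)
        assert len(np.unique(res.labels)) == 6

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            hcluster(np.zeros((4, 2)), 5)

    def test_planted_five_component_recovery(self):
        # 5-component, 217-cell mixture at 6-SD separation: ARI > 0.9
        aris = []
        for seed in range(20):
            X, truth = simulate_marker_mixture(rng=seed)
            res = hcluster(scale_markers(X), 5)
            aris.append(adjusted_rand_score(truth, res.labels))
        assert np.mean(aris) > 0.9

    def test_permutation_equivariance(self):
        X, _ = simulate_marker_mixture(n_cells=60, rng=3)
        scaled = scale_markers(X).to_numpy()
        perm = np.random.default_rng(0).permutation(60)
        res1 = hcluster(scaled, 5)
        res2 = hcluster(scaled[perm], 5)
        assert adjusted_rand_score(res1.labels[perm], res2.labels) == 1.0

    def test_affine_invariance_through_scaling(self):
        # per-marker affine transforms of raw AUCs do not change the partition
        X, _ = simulate_marker_mixture(n_cells=80, rng=5)
        Y = X * np.array([3.0, 0.5, 10.0, 1.7]) + np.array([5, -2, 0, 100])
        l1 = hcluster(scale_markers(X), 5).labels
        l2 = hcluster(scale_markers(Y), 5).labels
        assert adjusted_rand_score(l1, l2) == 1.0


class TestSpectral:
    def test_two_components_two_zero_eigenvalues(self):
        X = np.array([[0.0, 0], [1, 0], [0, 1],
                      [100, 100], [101, 100], [100, 101]])
        spec = spectral_spectrum(X, epsilon=2.0)
        assert np.sum(spec.eigenvalues < 1e-8) == 2
        assert spec.suggested_k == 2
        assert spec.n_components == 2

    def test_complete_graph_closed_form(self):
        # K_n: eigenvalues {0, n/(n-1) with multiplicity n-1}
        n = 8
        X = np.random.default_rng(0).normal(size=(n, 2))
        spec = spectral_spectrum(X, epsilon=1e6)
        expected = np.r_[0.0, np.full(n - 1, n / (n - 1))]
        assert np.allclose(np.sort(spec.eigenvalues), expected, atol=1e-9)
        assert spec.suggested_k == 1

    def test_eigenvalues_in_range_and_components_match_oracle(self):
        # union-find (scipy connected_components) as the independent oracle
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 3))
            eps = default_epsilon(X, 0.4)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                spec = spectral_spectrum(X, epsilon=eps)
            assert np.all(spec.eigenvalues >= -1e-9)
            assert np.all(spec.eigenvalues <= 2.0 + 1e-9)
            W = (squareform(pdist(X)) <= eps).astype(int)
            np.fill_diagonal(W, 0)
            n_comp, _ = connected_components(W, directed=False)
            assert spec.n_components == n_comp

    def test_planted_five_component_suggested_k(self):
        votes = []
        for seed in range(20):
            X, _ = simulate_marker_mixture(rng=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                spec = spectral_spectrum(scale_markers(X))
            votes.append(spec.suggested_k)
        assert sum(k == 5 for k in votes) >= 18

    def test_fully_disconnected_graph(self):
        X = np.array([[0.0, 0], [10, 0], [0, 10], [10, 10]])
        with pytest.warns(UserWarning):
            spec = spectral_spectrum(X, epsilon=0.5)
        assert spec.disconnected
        assert spec.suggested_k == spec.n_components == 4


class TestComposition:
    def test_counting_example(self):
        comp = cluster_composition([1, 1, 2, 2], ["A", "B", "A", "A"])
        assert comp.loc[1, "A"] == pytest.approx(0.5)
        assert comp.loc[1, "B"] == pytest.approx(0.5)
        assert comp.loc[2, "A"] == pytest.approx(1.0)

    def test_single_cluster_matches_global(self):
        origins = ["A"] * 7 + ["B"] * 3
        comp = cluster_composition([1] * 10, origins)
        assert comp.loc[1, "A"] == pytest.approx(0.7)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(1, 6, 200)
        origins = rng.choice(["t0903", "t0909"], 200)
        comp = cluster_composition(labels, origins)
        assert np.allclose(comp.sum(axis=1), 1.0)

    def test_planted_mixing_recovered(self):
        rng = np.random.default_rng(1)
        n = 400
        origins = np.where(rng.random(n) < 0.85, "t0909", "t0903")
        comp = cluster_composition(np.ones(n, dtype=int), origins)
        se = np.sqrt(0.85 * 0.15 / n)
        assert abs(comp.loc[1, "t0909"] - 0.85) < 4 * se


class TestPerClusterStats:
    @staticmethod
    def _records(n_pos, n_neg, rho_target, rng):
        # planted monotone anticorrelation via shared latent ranks
        z = rng.normal(size=n_pos)
        noise = rng.normal(size=n_pos)
        if rho_target == 0:
            y = noise
        else:
            w = abs(rho_target)
            y = np.sign(rho_target) * (w * z + np.sqrt(1 - w * w) * noise)
        rec = pd.DataFrame({
            "is_terbb2_pos": [True] * n_pos + [False] * n_neg,
            "auc_terbb2": np.r_[np.exp(z), np.full(n_neg, np.nan)],
            "auc_p-rs6": np.r_[np.exp(y), np.exp(rng.normal(size=n_neg))],
        })
        return rec

    def test_planted_anticorrelation_recovered(self):
        # planted rho = -0.6 with n = 22, recovered within +/-0.2 on average
        rhos = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            rec = self._records(22, 22, -0.6, rng)
            out = per_cluster_stats(np.ones(44, dtype=int), rec)
            rhos.append(out["rho"].iloc[0])
        assert np.mean(rhos) == pytest.approx(-0.6, abs=0.2)

    def test_null_mann_whitney_calibrated(self):
        # identical p-rs6 distributions: ~5% rejections at alpha = 0.05
        rejections = 0
        n_sim = 500
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            rec = self._records(15, 15, 0.0, rng)
            out = per_cluster_stats(np.ones(30, dtype=int), rec)
            rejections += out["mw_p"].iloc[0] < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.02)

    def test_tiny_group_not_computable(self):
        rng = np.random.default_rng(0)
        rec = self._records(2, 10, 0.0, rng)
        out = per_cluster_stats(np.ones(12, dtype=int), rec)
        assert np.isnan(out["rho"].iloc[0])
        assert np.isnan(out["mw_p"].iloc[0])

    def test_bh_adjustment_present(self):
        rng = np.random.default_rng(0)
        rec = pd.concat([self._records(10, 10, -0.5, rng) for _ in range(3)],
                        ignore_index=True)
        labels = np.repeat([1, 2, 3], 20)
        out = per_cluster_stats(labels, rec)
        assert {"rho_p_bh", "mw_p_bh"} <= set(out.columns)
        assert (out["mw_p_bh"].dropna() >= out["mw_p"].dropna() - 1e-12).all()
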