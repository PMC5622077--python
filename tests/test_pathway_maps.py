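"""Tanimoto kernels, kernel-GTM fitting/projection, kriging, top-set picks."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from gwas2drug.pathway_maps import (
    feature_dim,
    kernel_pca_embedding,
    kgtm_fit,
    krige_surface,
    membership_matrix,
    ordinary_kriging,
    project,
    select_top_sets,
    tanimoto_matrix,
    MapProjection,
)
from gwas2drug.synthetic import SyntheticConfig, gen_pathway_collection


def random_membership(rng, n_sets=20, n_genes=60, p=0.25):
    M = (rng.uniform(size=(n_sets, n_genes)) < p).astype(int)
    M[M.sum(axis=1) == 0, 0] = 1
    return M


def clustered_membership(rng, n_per=10, n_genes=80):
    """Two clusters built from disjoint templates with small perturbations."""
    M = np.zeros((2 * n_per, n_genes), dtype=int)
    t1, t2 = np.arange(0, 25), np.arange(40, 65)
    for i in range(n_per):
        M[i, t1] = 1
        M[n_per + i, t2] = 1
        for row in (i, n_per + i):
            flip = rng.choice(n_genes, 3, replace=False)
            M[row, flip] = 1 - M[row, flip]
    M[M.sum(axis=1) == 0, 0] = 1
    return M, np.r_[np.zeros(n_per, int), np.ones(n_per, int)]


class TestTanimoto:
    def test_identical_disjoint_partial(self):
        ids, M = membership_matrix({
            "a": {"g1", "g2", "g3"}, "b": {"g2", "g3", "g4"}, "c": {"g5"},
        })
        K = tanimoto_matrix(M)
        i, j, k = ids.index("a"), ids.index("b"), ids.index("c")
        assert K[i, i] == 1.0
        assert K[i, j] == pytest.approx(0.5)  # |{g2,g3}| / |{g1..g4}|
        assert K[i, k] == 0.0
        assert np.allclose(K, K.T)

    def test_empty_set_named(self):
        with pytest.raises(ValueError, match="rows \\[1\\]"):
            tanimoto_matrix(np.array([[1, 0], [0, 0]]))


class TestFeatureDim:
    def test_duplicated_sets_zero_variance(self):
        K = np.ones((5, 5))
        with pytest.warns(UserWarning):
            assert feature_dim(K) == 1

    def test_identity_kernel_loses_one_dim_to_centering(self):
        assert feature_dim(np.eye(10)) == 9

    def test_two_tight_clusters_low_dim(self, rng):
        M, _ = clustered_membership(rng)
        K = tanimoto_matrix(M)
        D = feature_dim(K)
        # oracle: full centered spectrum, count components for 99.5% mass
        n = K.shape[0]
        J = np.eye(n) - 1 / n
        lam = np.sort(np.clip(np.linalg.eigvalsh(J @ K @ J), 0, None))[::-1]
        expected = int(np.searchsorted(np.cumsum(lam), 0.995 * lam.sum() - 1e-12) + 1)
        assert D == expected
        assert lam[0] / lam.sum() > 0.5  # dominant cluster-separation axis

    def test_embedding_reproduces_kernel_distances(self, rng):
        M = random_membership(rng)
        K = tanimoto_matrix(M)
        X = kernel_pca_embedding(K, D=feature_dim(K))
        d_emb = ((X[:, None] - X[None, :]) ** 2).sum(-1)
        d_kern = np.diag(K)[:, None] + np.diag(K)[None, :] - 2 * K
        mask = d_kern > 1e-6
        rel = np.abs(d_emb[mask] - d_kern[mask]) / d_kern[mask]
        assert rel.max() <= 0.05


class TestKgtm:
    def test_square_root_grid_rules(self, rng):
        M = random_membership(rng, n_sets=16)
        model = kgtm_fit(tanimoto_matrix(M), seed=0)
        assert model.nodes.shape == (16, 2)   # k = 4
        assert model.centers.shape == (4, 2)  # m = 2

    def test_responsibilities_normalized(self, rng):
        M = random_membership(rng)
        model = kgtm_fit(tanimoto_matrix(M), seed=0)
        assert np.allclose(model.responsibilities.sum(axis=0), 1.0)

    def test_penalized_objective_monotone(self, rng):
        M = random_membership(rng, n_sets=25)
        model = kgtm_fit(tanimoto_matrix(M), seed=0)
        obj = np.array(model.objective_trace)
        assert (np.diff(obj) >= -1e-9 * np.maximum(1.0, np.abs(obj[:-1]))).all()

    def test_too_few_sets_rejected(self):
        with pytest.raises(ValueError):
            kgtm_fit(np.eye(3))

    def test_cluster_separation_on_planted_clusters(self, rng):
        M, labels = clustered_membership(rng)
        model = kgtm_fit(tanimoto_matrix(M), seed=1)
        proj = project(model)
        d = np.sqrt(((proj.coords[:, None] - proj.coords[None, :]) ** 2).sum(-1))
        within = d[labels[:, None] == labels[None, :]].mean()
        between = d[labels[:, None] != labels[None, :]].mean()
        assert within < between
        assert silhouette_score(proj.coords, labels) > 0

    def test_permutation_equivariance(self, rng):
        M = random_membership(rng, n_sets=16)
        K = tanimoto_matrix(M)
        perm = rng.permutation(16)
        c1 = project(kgtm_fit(K, seed=0)).coords
        c2 = project(kgtm_fit(K[np.ix_(perm, perm)], seed=0)).coords
        assert np.allclose(c1[perm], c2, atol=1e-6)


class TestProject:
    def test_duplicates_identical_coordinates(self, rng):
        M = random_membership(rng, n_sets=12)
        M = np.vstack([M, M[3], M[3]])  # duplicated gene-sets
        model = kgtm_fit(tanimoto_matrix(M), seed=0)
        coords = project(model).coords
        assert np.allclose(coords[3], coords[12], atol=1e-10)
        assert np.allclose(coords[12], coords[13], atol=1e-10)

    def test_coordinates_in_unit_square(self, rng):
        M = random_membership(rng)
        coords = project(kgtm_fit(tanimoto_matrix(M), seed=0)).coords
        assert (np.abs(coords) <= 1.0 + 1e-12).all()

    def test_dominant_responsibility_hits_node(self, rng):
        M = random_membership(rng, n_sets=9)
        model = kgtm_fit(tanimoto_matrix(M), seed=0)
        R = np.zeros_like(model.responsibilities)
        R[5, :] = 1.0
        model.responsibilities = R
        coords = project(model).coords
        assert np.allclose(coords, model.nodes[5])


class TestKriging:
    def proj(self, coords, colors):
        return MapProjection([str(i) for i in range(len(coords))],
                             np.asarray(coords, float), np.asarray(colors, float))

    def test_constant_field_constant_surface(self):
        p = self.proj([[-0.5, 0], [0.5, 0], [0, 0.5], [0, -0.5]], [2.0] * 4)
        _, _, surf, meta = krige_surface(p, grid_resolution=20)
        assert np.allclose(surf, 2.0)

    def test_exact_interpolation_at_data_points(self, rng):
        coords = rng.uniform(-0.9, 0.9, size=(8, 2))
        colors = rng.uniform(0, 5, size=8)
        p = self.proj(coords, colors)
        _, _, surf, meta = krige_surface(p, grid_resolution=10)
        pred = ordinary_kriging(coords, colors, coords,
                                (0.0, meta.get("variogram", {}).get("sill", 1.0),
                                 meta.get("variogram", {}).get("range", 0.5))) \
            if meta["method"] == "ordinary_kriging" else None
        if pred is not None:
            assert np.allclose(pred, colors, atol=1e-6)

    def test_two_point_predictions_bounded_on_segment(self):
        pts = np.array([[-0.5, 0.0], [0.5, 0.0]])
        vals = np.array([1.0, 3.0])
        targets = np.column_stack([np.linspace(-0.5, 0.5, 21), np.zeros(21)])
        pred = ordinary_kriging(pts, vals, targets, (0.0, 1.0, 0.4))
        assert (pred >= 1.0 - 1e-9).all() and (pred <= 3.0 + 1e-9).all()

    def test_fewer_than_three_points_rejected(self):
        p = self.proj([[0, 0], [1, 1]], [1.0, 2.0])
        with pytest.raises(ValueError):
            krige_surface(p)


class TestTopSets:
    def frame(self, n, ps=None):
        ps = ps if ps is not None else np.linspace(0.001, 0.9, n)
        return pd.DataFrame({"set_id": [f"s{i:03d}" for i in range(n)],
                             "p_competitive": ps})

    def test_takes_n_smallest(self):
        out = select_top_sets(self.frame(60), 50)
        assert len(out) == 50
        assert out["p_competitive"].is_monotonic_increasing

    def test_short_input_warns_returns_all(self):
        with pytest.warns(UserWarning):
            out = select_top_sets(self.frame(30), 50)
        assert len(out) == 30

    def test_boundary_tie_lexicographic(self):
        df = pd.DataFrame({"set_id": ["b", "a", "c"], "p_competitive": [0.5, 0.5, 0.1]})
        out = select_top_sets(df, 2)
        assert out["set_id"].tolist() == ["c", "a"]
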