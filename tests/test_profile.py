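"""Preprocessing, communality selection, embedding, clustering, Model/Results."""

import numpy as np
import pandas as pd
import pytest

from ovomorph import (
    MorphologyProfileModel,
    old_population,
    simulate_feature_table,
    young_population,
)
from ovomorph.morphometry import FeatureCatalog, FeatureMatrix
from ovomorph.profile import (
    characterize_clusters,
    embed,
    fit_kmeans,
    preprocess,
    select_features_communality,
)


def table_to_matrix(df: pd.DataFrame) -> FeatureMatrix:
    catalog = FeatureCatalog.from_columns({c: "cell" for c in df.columns})
    meta = pd.DataFrame({"cell_id": np.arange(len(df))})
    return FeatureMatrix(features=df, metadata=meta, catalog=catalog)


def brute_force_selection(X: np.ndarray, n_factors=2, threshold=0.5):
    """Independent oracle: explicit eigendecomposition of the correlation
    matrix via SVD of the standardized data."""
    Z = (X - X.mean(0)) / X.std(0)
    corr = Z.T @ Z / len(Z)
    vals, vecs = np.linalg.eig(corr)  # deliberately eig, not eigh
    order = np.argsort(vals.real)[::-1]
    vals, vecs = vals.real[order], vecs.real[:, order]
    load = vecs[:, :n_factors] * np.sqrt(vals[:n_factors])
    comm = (load**2).sum(axis=1)
    return comm, set(np.flatnonzero(comm >= threshold))


class TestPreprocess:
    def test_minmax_range(self):
        fm = simulate_feature_table([young_population()], 100, seed=0, n_noise=2)
        pre = preprocess(fm)
        assert (pre.data.to_numpy() >= -1 - 1e-12).all()
        assert (pre.data.to_numpy() <= 1 + 1e-12).all()

    def test_monotone_per_feature(self):
        fm = simulate_feature_table([young_population()], 200, seed=1)
        pre = preprocess(fm)
        for col in ("cell_area", "actin_sum"):
            x = fm.features[col].to_numpy()
            t = pre.data[col].to_numpy()
            order = np.argsort(x)
            assert (np.diff(t[order]) >= 0).all()

    def test_reapply_reproduces(self):
        fm = simulate_feature_table([young_population()], 50, seed=2, n_noise=1)
        pre = preprocess(fm)
        again = pre.apply(fm.features)
        assert np.allclose(again.to_numpy(), pre.data.to_numpy(), atol=1e-12)

    def test_constant_columns_dropped(self):
        df = pd.DataFrame({"a": np.random.default_rng(0).normal(size=20), "b": np.ones(20)})
        pre = preprocess(table_to_matrix(df))
        assert pre.dropped_constant == ["b"]
        assert list(pre.data.columns) == ["a"]

    def test_all_constant_errors(self):
        df = pd.DataFrame({"a": np.ones(20), "b": np.full(20, 2.0)})
        with pytest.raises(ValueError, match="constant"):
            preprocess(table_to_matrix(df))

    def test_zscore_alternative(self):
        fm = simulate_feature_table([young_population()], 100, seed=3)
        pre = preprocess(fm, scaler="zscore")
        assert np.allclose(pre.data.mean(), 0.0, atol=1e-9)
        assert np.allclose(pre.data.std(ddof=0), 1.0, atol=1e-9)


def planted_factor_table(n=400, seed=0):
    """8 features: 5 noisy mixtures of 2 latent factors, 3 pure noise."""
    rng = np.random.default_rng(seed)
    f1, f2 = rng.normal(size=(2, n))
    cols = {}
    weights = [(1.0, 0.2), (0.8, -0.5), (0.1, 1.0), (-0.7, 0.6), (0.9, 0.9)]
    for i, (w1, w2) in enumerate(weights):
        cols[f"signal_{i}"] = w1 * f1 + w2 * f2 + 0.25 * rng.normal(size=n)
    for i in range(3):
        cols[f"noise_{i}"] = rng.normal(size=n)
    return pd.DataFrame(cols)


class TestCommunalitySelection:
    def test_matches_brute_force_oracle(self):
        df = planted_factor_table()
        pre = preprocess(table_to_matrix(df), scaler="zscore")
        sel = select_features_communality(pre)
        comm_oracle, _ = brute_force_selection(pre.data.to_numpy())
        assert np.allclose(sel.communality.to_numpy(), comm_oracle, atol=1e-9)

    def test_communality_is_sum_of_squared_loadings(self):
        df = planted_factor_table(seed=1)
        sel = select_features_communality(preprocess(table_to_matrix(df)))
        recomputed = (sel.loadings**2).sum(axis=1)
        assert np.allclose(recomputed, sel.communality, atol=1e-12)

    def test_planted_noise_features_dropped(self):
        df = planted_factor_table(seed=2)
        sel = select_features_communality(preprocess(table_to_matrix(df)), threshold=0.5)
        dropped = set(df.columns) - set(sel.retained)
        assert dropped == {"noise_0", "noise_1", "noise_2"}
        worst3 = set(sel.communality.nsmallest(3).index)
        assert worst3 == dropped

    def test_communality_in_unit_interval(self):
        df = planted_factor_table(seed=3)
        sel = select_features_communality(preprocess(table_to_matrix(df)))
        assert (sel.communality >= 0).all()
        assert (sel.communality <= 1 + 1e-9).all()

    def test_principal_axis_option(self):
        df = planted_factor_table(seed=4)
        sel = select_features_communality(
            preprocess(table_to_matrix(df)), method="principal_axis"
        )
        dropped = set(df.columns) - set(sel.retained)
        assert dropped == {"noise_0", "noise_1", "noise_2"}

    def test_too_few_cells_errors(self):
        df = planted_factor_table(n=8)
        with pytest.raises(ValueError, match="10 cells"):
            select_features_communality(preprocess(table_to_matrix(df)))


class TestEmbed:
    def test_pca_preserves_distances_for_2d_input(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 2))
        emb = embed(X, method="pca")
        d_in = np.linalg.norm(X[:, None] - X[None], axis=-1)
        d_out = np.linalg.norm(emb.values[:, None] - emb.values[None], axis=-1)
        assert np.allclose(d_in, d_out, atol=1e-9)

    def test_pca_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 5))
        a = embed(X, method="pca", seed=0)
        b = embed(X, method="pca", seed=99)  # seed irrelevant for pca
        assert np.array_equal(a.values, b.values)

    def test_umap_seed_reproducible(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(i * 10, 1, size=(30, 4)) for i in range(3)])
        a = embed(X, method="umap", seed=5)
        b = embed(X, method="umap", seed=5)
        assert np.allclose(a.values, b.values)

    def test_umap_small_n_advises_pca(self):
        with pytest.raises(ValueError, match="pca"):
            embed(np.zeros((5, 3)), method="umap")

    def test_separated_subtypes_silhouette(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(i * 12, 1, size=(40, 6)) for i in range(3)])
        labels = np.repeat([0, 1, 2], 40)
        emb = embed(X, method="umap", seed=0)
        assert silhouette_score(emb.values, labels) >= 0.5


def gaussian_mixture(k, n_per, dim, sep, rng):
    centers = rng.normal(0, sep / np.sqrt(2), (k, dim))
    for _ in range(200):
        d = np.linalg.norm(centers[:, None] - centers[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() >= sep:
            break
        i = np.unravel_index(np.argmin(d), d.shape)[0]
        centers[i] = rng.normal(0, sep, dim)
    return np.vstack([c + rng.normal(0, 1, (n_per, dim)) for c in centers])


class TestFitKmeans:
    def test_auto_recovers_three_clusters(self):
        from sklearn.metrics import silhouette_score
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(0)
        X = gaussian_mixture(3, 50, 4, 10.0, rng)
        cm = fit_kmeans(X, k="auto", seed=0)
        assert cm.k == 3
        # independent oracle: silhouette-maximizing k on the same data
        best = max(range(2, 10), key=lambda k: silhouette_score(
            X, KMeans(n_clusters=k, n_init=10, random_state=1).fit_predict(X)))
        assert cm.k == best

    def test_duplication_invariance(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(1)
        X = gaussian_mixture(3, 40, 4, 10.0, rng)
        a = fit_kmeans(X, k="auto", seed=0)
        b = fit_kmeans(np.vstack([X, X]), k="auto", seed=0)
        assert a.k == b.k
        assert adjusted_rand_score(np.tile(a.labels, 2), b.labels) == 1.0

    def test_fixed_k_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 6))
        a = fit_kmeans(X, k=8, seed=3)
        b = fit_kmeans(X, k=8, seed=3)
        assert a.k == 8
        assert np.array_equal(a.labels, b.labels)
        assert set(np.unique(a.labels)) <= set(range(1, 9))

    def test_inertia_non_increasing(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(150, 5))
        cm = fit_kmeans(X, k="auto", k_range=range(2, 12), seed=0)
        vals = [cm.inertia_curve[k] for k in sorted(cm.inertia_curve)]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_feature_order_permutation_invariance(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(4)
        X = gaussian_mixture(4, 40, 5, 9.0, rng)
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)])
        a = fit_kmeans(df, k=4, seed=0)
        b = fit_kmeans(df[["f3", "f0", "f4", "f2", "f1"]], k=4, seed=0)
        assert adjusted_rand_score(a.labels, b.labels) == 1.0

    def test_k_larger_than_n_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            fit_kmeans(np.zeros((5, 2)), k=10)


class TestCharacterizeClusters:
    def test_single_cluster_equals_whole_sample(self):
        fm = simulate_feature_table([young_population()], 100, seed=0)
        labels = np.ones(100, dtype=int)
        out = characterize_clusters(fm, labels, ["cell_area", "actin_sum"])
        assert out.loc[1, "cell_area_median"] == fm.features["cell_area"].median()
        assert out.loc[1, "n"] == 100

    def test_medians_match_direct_groupby(self):
        fm = simulate_feature_table([young_population(), old_population()], 100, seed=1)
        rng = np.random.default_rng(0)
        labels = rng.integers(1, 5, size=fm.n_cells)
        out = characterize_clusters(fm, labels, ["cell_area"])
        direct = fm.features.groupby(labels)["cell_area"].median()
        assert np.allclose(out["cell_area_median"], direct, atol=1e-12)

    def test_empty_cluster_reported(self):
        fm = simulate_feature_table([young_population()], 20, seed=2)
        labels = np.full(20, 3)  # clusters 1 and 2 empty
        out = characterize_clusters(fm, labels, ["cell_area"])
        assert out.loc[1, "n"] == 0
        assert out.loc[3, "n"] == 20


class TestModelResults:
    def test_fit_summary_and_tables(self):
        fm = simulate_feature_table([young_population(), old_population()], 250, seed=0,
                                    n_noise=3)
        model = MorphologyProfileModel(fm, embed_method="pca", k=8)
        res = model.fit(seed=0)
        assert res.k == 8
        text = res.summary()
        assert "features retained" in text
        table = res.cell_table()
        assert {"dim1", "dim2", "cluster", "group"} <= set(table.columns)
        assert len(table) == fm.n_cells
        assert res.selection.communality[[f"noise_{i}" for i in range(3)]].max() < 0.5

    def test_embedding_space_clustering_flag(self):
        fm = simulate_feature_table([young_population()], 150, seed=1)
        res = MorphologyProfileModel(fm, embed_method="pca", k=4,
                                     cluster_space="embedding").fit(seed=0)
        assert res.clusters.centroids.shape[1] == 2  # clustered in 2D

    def test_from_dataframe_roundtrip(self):
        df = planted_factor_table(n=60)
        df["cell_id"] = np.arange(60)
        df["group"] = "g"
        model = MorphologyProfileModel.from_dataframe(df, embed_method="pca", k=2)
        res = model.fit(seed=0)
        assert len(res.labels) == 60
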