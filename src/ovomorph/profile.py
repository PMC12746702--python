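"""Morphological profiling: preprocessing, communality-based feature
selection, 2D embedding, and k-means clustering with data-driven k.

The workflow mirrors a standard single-cell morphometry analysis: per-feature
log transform and scaling to [-1, 1]; a two-factor principal-component
factoring of the feature correlation matrix whose *communalities* (sum of
squared loadings over the two factors) gauge how much of the population
variance each feature carries — features below a communality threshold
(default 0.5) are dropped as noise; a 2D embedding (UMAP, or PCA for a fully
deterministic alternative); and k-means over the selected features with k
chosen by a plateau rule on the inertia and mean-silhouette curves.

The module exposes both the individual operations and a statsmodels-style
pair :class:`MorphologyProfileModel` / :class:`MorphologyProfileResults`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .morphometry import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessedMatrix",
    "SelectionResult",
    "Embedding",
    "ClusterModel",
    "preprocess",
    "select_features_communality",
    "embed",
    "fit_kmeans",
    "characterize_clusters",
    "MorphologyProfileModel",
    "MorphologyProfileResults",
]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

@dataclass
class FeatureTransform:
    log_kind: str  # "log" | "signed_log1p"
    lo: float  # min (minmax) or mean (zscore) of the logged values
    hi: float  # max (minmax) or sd (zscore)


@dataclass
class PreprocessedMatrix:
    """Transformed cells x features table plus the per-feature transform
    record needed to re-apply the mapping to new cells."""

    data: pd.DataFrame
    transforms: dict[str, FeatureTransform]
    scaler: str
    dropped_constant: list[str] = field(default_factory=list)
    source: FeatureMatrix | None = None

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def apply(self, features: pd.DataFrame) -> pd.DataFrame:
        """Apply the stored transform to a new feature table."""
        out = {}
        for name, tr in self.transforms.items():
            x = features[name].to_numpy(dtype=float)
            v = np.log(x) if tr.log_kind == "log" else np.sign(x) * np.log1p(np.abs(x))
            if self.scaler == "minmax":
                span = tr.hi - tr.lo
                out[name] = 2.0 * (v - tr.lo) / span - 1.0 if span > 0 else np.zeros_like(v)
            else:
                out[name] = (v - tr.lo) / tr.hi if tr.hi > 0 else np.zeros_like(v)
        return pd.DataFrame(out, index=features.index)


def preprocess(features: FeatureMatrix, scaler: str = "minmax") -> PreprocessedMatrix:
    """Log-transform and scale every feature.

    Strictly positive features get a plain log; features with zero or
    negative values get the signed log ``sign(x) * log1p(|x|)``. The default
    scaler then maps each feature to [-1, 1] by min-max; ``scaler="zscore"``
    standardizes instead. Constant columns are dropped with a warning.
    """
    if scaler not in ("minmax", "zscore"):
        raise ValueError(f"unknown scaler '{scaler}'")
    if features.n_cells < 2:
        raise ValueError("need at least 2 cells to preprocess")

    transforms: dict[str, FeatureTransform] = {}
    cols: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for name in features.features.columns:
        x = features.features[name].to_numpy(dtype=float)
        if np.all(x > 0):
            kind, v = "log", np.log(x)
        else:
            kind, v = "signed_log1p", np.sign(x) * np.log1p(np.abs(x))
        if scaler == "minmax":
            lo, hi = float(v.min()), float(v.max())
            if hi - lo < 1e-12:
                dropped.append(name)
                continue
            cols[name] = 2.0 * (v - lo) / (hi - lo) - 1.0
        else:
            lo, hi = float(v.mean()), float(v.std())
            if hi < 1e-12:
                dropped.append(name)
                continue
            cols[name] = (v - lo) / hi
        transforms[name] = FeatureTransform(kind, lo, hi)
    if dropped:
        logger.warning("dropped %d constant feature(s): %s", len(dropped), dropped[:10])
    if not cols:
        raise ValueError("all features are constant; nothing to preprocess")
    return PreprocessedMatrix(
        data=pd.DataFrame(cols, index=features.features.index),
        transforms=transforms,
        scaler=scaler,
        dropped_constant=dropped,
        source=features,
    )


# ---------------------------------------------------------------------------
# communality-based feature selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Two-factor loadings, per-feature communalities, and the retained set."""

    loadings: pd.DataFrame  # features x n_factors
    communality: pd.Series
    retained: list[str]
    threshold: float
    eigenvalues: np.ndarray

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def select_features_communality(
    matrix: PreprocessedMatrix,
    n_factors: int = 2,
    threshold: float = 0.5,
    method: str = "principal_component",
) -> SelectionResult:
    """Select features whose two-factor communality reaches ``threshold``.

    Factors are extracted from the feature correlation matrix by
    principal-component factoring (loadings = eigenvectors scaled by the
    square root of their eigenvalues); ``method="principal_axis"`` iterates
    with communality estimates on the diagonal instead. The communality of
    feature j is the sum of its squared loadings; features below the
    threshold are dropped as carrying little of the population variance.
    """
    X = matrix.data.to_numpy(dtype=float)
    names = list(matrix.data.columns)
    if len(names) < n_factors + 1:
        raise ValueError(f"need at least {n_factors + 1} non-constant features, have {len(names)}")
    if X.shape[0] < 10:
        raise ValueError(f"need at least 10 cells, have {X.shape[0]}")

    corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)

    if method == "principal_axis":
        loadings, eigvals = _principal_axis(corr, n_factors)
    elif method == "principal_component":
        eigvals, eigvecs = np.linalg.eigh(corr)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        if np.sum(eigvals > 0) < n_factors:
            raise ValueError(
                f"correlation matrix has fewer than {n_factors} positive eigenvalues"
            )
        loadings = eigvecs[:, :n_factors] * np.sqrt(eigvals[:n_factors])
        eigvals = eigvals[:n_factors]
    else:
        raise ValueError(f"unknown extraction method '{method}'")

    communality = pd.Series((loadings**2).sum(axis=1), index=names, name="communality")
    retained = [n for n in names if communality[n] >= threshold]
    if len(retained) < n_factors:
        # degenerate threshold: keep the top features so downstream stages run
        retained = list(communality.sort_values(ascending=False).index[:n_factors])
        logger.warning("fewer than %d features reached communality %.2f; keeping top %d",
                       n_factors, threshold, n_factors)
    cols = [f"factor_{i + 1}" for i in range(n_factors)]
    return SelectionResult(
        loadings=pd.DataFrame(loadings, index=names, columns=cols),
        communality=communality,
        retained=retained,
        threshold=threshold,
        eigenvalues=eigvals,
    )


def _principal_axis(corr: np.ndarray, n_factors: int, n_iter: int = 50, tol: float = 1e-6):
    """Iterated principal-axis factoring: squared multiple correlations start
    the communality estimates on the diagonal."""
    r = corr.copy()
    try:
        inv = np.linalg.inv(corr)
        smc = 1.0 - 1.0 / np.diag(inv)
    except np.linalg.LinAlgError:
        smc = np.full(corr.shape[0], 0.5)
    comm = np.clip(smc, 0.0, 1.0)
    loadings = None
    for _ in range(n_iter):
        np.fill_diagonal(r, comm)
        eigvals, eigvecs = np.linalg.eigh(r)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        if np.sum(eigvals > 0) < n_factors:
            raise ValueError(f"reduced correlation matrix has fewer than {n_factors} positive eigenvalues")
        loadings = eigvecs[:, :n_factors] * np.sqrt(np.maximum(eigvals[:n_factors], 0.0))
        new_comm = (loadings**2).sum(axis=1)
        if np.max(np.abs(new_comm - comm)) < tol:
            comm = new_comm
            break
        comm = new_comm
    return loadings, eigvals[:n_factors]


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

@dataclass
class Embedding:
    """2D coordinates per cell (columns dim1, dim2)."""

    coords: pd.DataFrame
    method: str
    seed: int

    @property
    def values(self) -> np.ndarray:
        return self.coords[["dim1", "dim2"]].to_numpy(dtype=float)


def embed(matrix, method: str = "umap", seed: int = 0, features: list[str] | None = None) -> Embedding:
    """Embed cells to 2D by UMAP (seeded) or PCA (deterministic).

    ``matrix`` is a PreprocessedMatrix, DataFrame or array; ``features``
    restricts to the retained columns. The PCA sign convention makes the
    largest-magnitude loading of each component positive.
    """
    if isinstance(matrix, PreprocessedMatrix):
        df = matrix.data
    elif isinstance(matrix, pd.DataFrame):
        df = matrix
    else:
        df = pd.DataFrame(np.asarray(matrix, dtype=float))
    if features is not None:
        df = df[features]
    X = df.to_numpy(dtype=float)

    if method == "pca":
        pca = PCA(n_components=2, svd_solver="full")
        coords = pca.fit_transform(X)
        for i in range(2):
            comp = pca.components_[i]
            if comp[np.argmax(np.abs(comp))] < 0:
                coords[:, i] *= -1.0
    elif method == "umap":
        if X.shape[0] < 10:
            raise ValueError("fewer than 10 cells: UMAP is unreliable; use method='pca'")
        import umap  # deferred: heavy import

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(n_components=2, random_state=seed, n_jobs=1)
            coords = reducer.fit_transform(X)
    else:
        raise ValueError(f"unknown embedding method '{method}'")
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("embedding produced non-finite coordinates")
    out = pd.DataFrame(coords, columns=["dim1", "dim2"], index=df.index)
    return Embedding(coords=out, method=method, seed=seed)


# ---------------------------------------------------------------------------
# k-means with plateau-rule k selection
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    """k-means fit plus the k-scan diagnostics used for model selection."""

    k: int
    labels: np.ndarray  # values in {1..k}
    centroids: np.ndarray
    inertia_curve: dict[int, float]
    silhouette_curve: dict[int, float]
    seed: int
    chosen_by: str = "plateau"

    def fractional_sizes(self) -> np.ndarray:
        return np.bincount(self.labels - 1, minlength=self.k) / len(self.labels)


def _fit_single_k(X, k, seed, n_init, prev_fit: KMeans | None):
    """KMeans at one k; an extra warm-start init (previous centroids plus the
    worst-fit point) guarantees the inertia curve never increases with k."""
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    km.fit(X)
    if prev_fit is not None and km.inertia_ > prev_fit.inertia_:
        d = np.linalg.norm(X - prev_fit.cluster_centers_[prev_fit.labels_], axis=1)
        init = np.vstack([prev_fit.cluster_centers_, X[np.argmax(d)]])
        km2 = KMeans(n_clusters=k, init=init, n_init=1, random_state=seed)
        km2.fit(X)
        if km2.inertia_ < km.inertia_:
            km = km2
    return km


def fit_kmeans(
    data,
    k: int | str = "auto",
    k_range: range = range(2, 16),
    seed: int = 0,
    n_init: int = 10,
    features: list[str] | None = None,
    inertia_drop: float = 0.10,
    silhouette_slack: float = 0.01,
) -> ClusterModel:
    """k-means clustering with k chosen by a plateau rule when ``k="auto"``.

    The scan over ``k_range`` records the inertia and mean silhouette at each
    k; the chosen k is the smallest whose relative inertia drop to k+1 falls
    below ``inertia_drop`` while its silhouette is within
    ``silhouette_slack`` of the running maximum. A fixed integer k skips the
    scan.
    """
    if isinstance(data, PreprocessedMatrix):
        df = data.data
    elif isinstance(data, Embedding):
        df = data.coords
    elif isinstance(data, pd.DataFrame):
        df = data
    else:
        df = pd.DataFrame(np.asarray(data, dtype=float))
    if features is not None:
        df = df[features]
    X = df.to_numpy(dtype=float)
    n = X.shape[0]

    if k != "auto":
        k = int(k)
        if k > n:
            raise ValueError(f"k={k} exceeds the number of cells ({n})")
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        sil = silhouette_score(X, km.labels_, sample_size=min(n, 5000), random_state=seed) if k > 1 else float("nan")
        return ClusterModel(
            k=k,
            labels=km.labels_ + 1,
            centroids=km.cluster_centers_,
            inertia_curve={k: float(km.inertia_)},
            silhouette_curve={k: float(sil)},
            seed=seed,
            chosen_by="fixed",
        )

    ks = [kk for kk in k_range if kk <= n - 1]
    if len(ks) < 2:
        raise ValueError(f"k_range {list(k_range)} has fewer than 2 feasible values for n={n}")
    fits: dict[int, KMeans] = {}
    inertia: dict[int, float] = {}
    sil: dict[int, float] = {}
    prev = None
    for kk in ks:
        km = _fit_single_k(X, kk, seed, n_init, prev)
        fits[kk] = km
        inertia[kk] = float(km.inertia_)
        sil[kk] = float(
            silhouette_score(X, km.labels_, sample_size=min(n, 5000), random_state=seed)
        )
        prev = km

    drops = {
        kk: (inertia[kk] - inertia[ks[i + 1]]) / inertia[kk] if inertia[kk] > 0 else 0.0
        for i, kk in enumerate(ks[:-1])
    }
    chosen = None
    running_max = -np.inf
    for kk in ks[:-1]:
        running_max = max(running_max, sil[kk])
        if drops[kk] < inertia_drop and sil[kk] >= running_max - silhouette_slack:
            chosen = kk
            break
    chosen_by = "plateau"
    if chosen is None:
        # no k plateaued on both curves: best silhouette among k's that are
        # not grossly under-merged (a forward inertia drop >= 25% means k+1
        # still splits a real cluster)
        pool = [kk for kk in ks[:-1] if drops[kk] < 0.25] or list(sil)
        chosen = max(pool, key=sil.get)
        chosen_by = "max_silhouette_fallback"
        logger.info("no joint plateau in k scan; falling back to max-silhouette k=%d", chosen)

    km = fits[chosen]
    return ClusterModel(
        k=chosen,
        labels=km.labels_ + 1,
        centroids=km.cluster_centers_,
        inertia_curve=inertia,
        silhouette_curve=sil,
        seed=seed,
        chosen_by=chosen_by,
    )


def characterize_clusters(
    features: FeatureMatrix,
    labels: np.ndarray,
    feature_names: list[str] = ("nucleus_area", "cell_area", "vimentin_sum", "actin_sum"),
) -> pd.DataFrame:
    """Per-cluster n, median and IQR of the requested features, plus a
    descending-median rank per feature (rank 1 = largest)."""
    labels = np.asarray(labels)
    if len(labels) != features.n_cells:
        raise ValueError("labels do not align with the feature matrix")
    present = [f for f in feature_names if f in features.features.columns]
    df = features.features[present].copy()
    df["cluster"] = labels
    g = df.groupby("cluster")

    out = pd.DataFrame({"n": g.size()})
    for f in present:
        out[f"{f}_median"] = g[f].median()
        out[f"{f}_iqr"] = g[f].quantile(0.75) - g[f].quantile(0.25)
        out[f"{f}_rank"] = out[f"{f}_median"].rank(ascending=False).astype(int)
    all_clusters = np.arange(1, labels.max() + 1)
    out = out.reindex(all_clusters)
    out["n"] = out["n"].fillna(0).astype(int)
    return out


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class MorphologyProfileModel:
    """Full morphological-profiling model over a feature matrix.

    ``fit()`` runs preprocessing, communality selection, embedding and
    clustering, and returns a :class:`MorphologyProfileResults`.

    Parameters
    ----------
    features : FeatureMatrix
        Cells x features with per-cell metadata.
    scaler : {"minmax", "zscore"}
        Per-feature scaling after the log transform.
    n_factors, communality_threshold
        Two-factor communality selection settings.
    embed_method : {"umap", "pca"}
    k : int or "auto"
        Cluster count, or plateau-rule selection over ``k_range``.
    cluster_space : {"features", "embedding"}
        Whether k-means runs on the selected preprocessed features (default)
        or on the 2D embedding coordinates.
    """

    def __init__(
        self,
        features: FeatureMatrix,
        scaler: str = "minmax",
        n_factors: int = 2,
        communality_threshold: float = 0.5,
        embed_method: str = "umap",
        k: int | str = "auto",
        k_range: range = range(2, 16),
        cluster_space: str = "features",
        n_init: int = 10,
    ):
        if cluster_space not in ("features", "embedding"):
            raise ValueError(f"unknown cluster_space '{cluster_space}'")
        self.features = features
        self.scaler = scaler
        self.n_factors = n_factors
        self.communality_threshold = communality_threshold
        self.embed_method = embed_method
        self.k = k
        self.k_range = k_range
        self.cluster_space = cluster_space
        self.n_init = n_init

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        metadata_columns: list[str] = ("cell_id", "group"),
        **kwargs,
    ) -> "MorphologyProfileModel":
        """Build from a flat table whose non-metadata columns are features."""
        from .morphometry import FeatureCatalog

        meta_cols = [c for c in metadata_columns if c in df.columns]
        feats = df.drop(columns=meta_cols)
        catalog = FeatureCatalog.from_columns({c: "cell" for c in feats.columns})
        fm = FeatureMatrix(features=feats.reset_index(drop=True),
                           metadata=df[meta_cols].reset_index(drop=True),
                           catalog=catalog)
        return cls(fm, **kwargs)

    def fit(self, seed: int = 0) -> "MorphologyProfileResults":
        pre = preprocess(self.features, scaler=self.scaler)
        sel = select_features_communality(
            pre, n_factors=self.n_factors, threshold=self.communality_threshold
        )
        emb = embed(pre, method=self.embed_method, seed=seed, features=sel.retained)
        cluster_input = emb if self.cluster_space == "embedding" else pre.data[sel.retained]
        clusters = fit_kmeans(
            cluster_input, k=self.k, k_range=self.k_range, seed=seed, n_init=self.n_init
        )
        return MorphologyProfileResults(
            model=self, preprocessed=pre, selection=sel, embedding=emb, clusters=clusters, seed=seed
        )


@dataclass
class MorphologyProfileResults:
    """Fitted morphological profile: transforms, selection, embedding,
    clusters, and their diagnostics."""

    model: MorphologyProfileModel
    preprocessed: PreprocessedMatrix
    selection: SelectionResult
    embedding: Embedding
    clusters: ClusterModel
    seed: int

    @property
    def labels(self) -> np.ndarray:
        return self.clusters.labels

    @property
    def k(self) -> int:
        return self.clusters.k

    def cell_table(self) -> pd.DataFrame:
        """Per-cell metadata + embedding coordinates + cluster label."""
        out = self.model.features.metadata.copy().reset_index(drop=True)
        out["dim1"] = self.embedding.coords["dim1"].to_numpy()
        out["dim2"] = self.embedding.coords["dim2"].to_numpy()
        out["cluster"] = self.labels
        return out

    def characterize(self, feature_names=("nucleus_area", "cell_area", "vimentin_sum", "actin_sum")) -> pd.DataFrame:
        return characterize_clusters(self.model.features, self.labels, feature_names)

    def summary(self) -> str:
        sel, cl = self.selection, self.clusters
        n_in = len(self.preprocessed.data.columns)
        lines = [
            "Morphological profile fit",
            "=" * 25,
            f"cells:               {self.preprocessed.n_cells}",
            f"features in:         {n_in} (+{len(self.preprocessed.dropped_constant)} constant dropped)",
            f"features retained:   {sel.n_retained} (communality >= {sel.threshold})",
            f"embedding:           {self.embedding.method} (seed {self.seed})",
            f"k:                   {cl.k} ({cl.chosen_by})",
            f"silhouette at k:     {cl.silhouette_curve.get(cl.k, float('nan')):.3f}",
            f"cluster sizes:       {np.bincount(self.labels - 1, minlength=cl.k).tolist()}",
        ]
        return "\n".join(lines)

    def plot_embedding(self, color_by: str = "cluster", ax=None):
        from .plotting import plot_embedding

        return plot_embedding(self.cell_table(), color_by=color_by, ax=ax)

    def plot_k_diagnostics(self, ax=None):
        from .plotting import plot_k_diagnostics

        return plot_k_diagnostics(self.clusters, ax=ax)
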