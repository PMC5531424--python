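"""Population-structure analysis of spike-normalised expression matrices.

The number of statistically distinguishable subpopulations is chosen by
the gap statistic: for each candidate k, the log within-cluster
dispersion ``log W_k`` of a k-means fit is compared with its expectation
under B reference datasets drawn uniformly over the PCA-aligned bounding
box of the data (the rotation-robust reference null).  With

    Gap(k) = E*[log W_k] - log W_k,
    s_k    = sd*[log W_k] * sqrt(1 + 1/B),

the selected k is the smallest k with ``Gap(k) >= Gap(k+1) - s_{k+1}``.

A transient rise in the number of strongly correlated gene pairs
(Pearson r above a threshold, default 0.8) inside a cell group is used as
an early-warning indicator of an imminent state transition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .qpcr import ExpressionMatrix

__all__ = [
    "GapStatisticResult",
    "ClusterAssignment",
    "CorrelationNetwork",
    "GapKMeans",
    "select_k_gap",
    "cluster_cells",
    "correlation_burst",
    "pca_contributions",
    "embed_2d",
]


def _as_array(matrix) -> tuple[np.ndarray, pd.Index]:
    if isinstance(matrix, ExpressionMatrix):
        return matrix.values.to_numpy(float), matrix.values.index
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(float), matrix.index
    X = np.asarray(matrix, float)
    return X, pd.RangeIndex(len(X))


@dataclass
class GapStatisticResult:
    """Gap curve over candidate k values and the selected k."""

    k_values: np.ndarray
    log_w: np.ndarray
    e_log_w: np.ndarray
    gap: np.ndarray
    s_k: np.ndarray
    selected_k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "log_w": self.log_w,
                "e_log_w": self.e_log_w,
                "gap": self.gap,
                "s_k": self.s_k,
            }
        ).set_index("k")


@dataclass
class ClusterAssignment:
    """Cluster labels (1..k) with centroids and total inertia."""

    labels: pd.Series
    centroids: np.ndarray
    inertia: float
    k: int


def _inertia(X: np.ndarray, k: int, n_init: int, seed) -> float:
    if k == 1:
        return float(((X - X.mean(axis=0)) ** 2).sum())
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    km.fit(X)
    return float(km.inertia_)


class GapKMeans(ClusterMixin, BaseEstimator):
    """K-means with the cluster number selected by the gap statistic.

    Parameters
    ----------
    k_max : int
        Largest candidate k (candidates are 1..k_max).
    n_refs : int
        Number of reference datasets B drawn uniformly over the
        PCA-aligned bounding box of the data.
    n_init : int
        K-means restarts inside the gap computation (data and references).
    n_init_final : int
        Restarts for the final fit at the selected k.
    random_state : int or None
        Seeds the reference draws and every k-means restart.

    Attributes
    ----------
    gap_result_ : GapStatisticResult
    n_clusters_ : int
    labels_, cluster_centers_, inertia_ : final k-means fit.
    """

    def __init__(
        self,
        k_max: int = 6,
        n_refs: int = 50,
        n_init: int = 10,
        n_init_final: int = 25,
        random_state: int | None = 0,
    ) -> None:
        self.k_max = k_max
        self.n_refs = n_refs
        self.n_init = n_init
        self.n_init_final = n_init_final
        self.random_state = random_state

    def fit(self, X, y=None) -> "GapKMeans":
        X, _ = _as_array(X)
        n, p = X.shape
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if n < self.k_max + 1:
            raise ValueError(f"need at least k_max+1={self.k_max + 1} cells, got {n}")
        rng = np.random.default_rng(self.random_state)
        ks = np.arange(1, self.k_max + 1)

        if np.allclose(X.var(axis=0), 0.0):
            warnings.warn("constant matrix: selecting k = 1", stacklevel=2)
            self.gap_result_ = GapStatisticResult(
                ks, np.full(len(ks), -np.inf), np.zeros(len(ks)),
                np.zeros(len(ks)), np.zeros(len(ks)), 1,
            )
            self.n_clusters_ = 1
        else:
            eps = 1e-12
            log_w = np.array(
                [np.log(max(_inertia(X, k, self.n_init, int(rng.integers(2**31)))
                            , eps)) for k in ks]
            )
            # PCA-aligned bounding box: rotate, sample uniform, rotate back
            mean = X.mean(axis=0)
            Xc = X - mean
            _, _, vt = np.linalg.svd(Xc, full_matrices=False)
            Xp = Xc @ vt.T
            lo, hi = Xp.min(axis=0), Xp.max(axis=0)
            ref_log_w = np.empty((self.n_refs, len(ks)))
            for b in range(self.n_refs):
                Z = rng.uniform(lo, hi, size=Xp.shape) @ vt + mean
                for j, k in enumerate(ks):
                    ref_log_w[b, j] = np.log(
                        max(_inertia(Z, k, self.n_init, int(rng.integers(2**31))), eps)
                    )
            e_log_w = ref_log_w.mean(axis=0)
            gap = e_log_w - log_w
            s_k = ref_log_w.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / self.n_refs)

            selected = int(ks[-1])
            for j in range(len(ks) - 1):
                if gap[j] >= gap[j + 1] - s_k[j + 1]:
                    selected = int(ks[j])
                    break
            self.gap_result_ = GapStatisticResult(ks, log_w, e_log_w, gap, s_k, selected)
            self.n_clusters_ = selected

        if self.n_clusters_ == 1:
            self.labels_ = np.zeros(n, dtype=int)
            self.cluster_centers_ = X.mean(axis=0, keepdims=True)
            self.inertia_ = float(((X - self.cluster_centers_) ** 2).sum())
        else:
            km = KMeans(
                n_clusters=self.n_clusters_,
                n_init=self.n_init_final,
                random_state=self.random_state,
            ).fit(X)
            self.labels_ = km.labels_
            self.cluster_centers_ = km.cluster_centers_
            self.inertia_ = float(km.inertia_)
        return self


def select_k_gap(
    matrix,
    k_max: int = 6,
    n_refs: int = 50,
    seed: int | None = 0,
) -> GapStatisticResult:
    """Choose the number of clusters by the gap statistic."""
    est = GapKMeans(k_max=k_max, n_refs=n_refs, random_state=seed)
    est.fit(matrix)
    return est.gap_result_


def cluster_cells(matrix, k: int, seed: int | None = 0) -> ClusterAssignment:
    """K-means assignment at a given k (best of 25 restarts by inertia)."""
    X, index = _as_array(matrix)
    if k > len(X):
        raise ValueError(f"k={k} exceeds the number of cells ({len(X)})")
    if k == 1:
        centroid = X.mean(axis=0, keepdims=True)
        inertia = float(((X - centroid) ** 2).sum())
        labels = pd.Series(1, index=index, name="cluster")
        return ClusterAssignment(labels, centroid, inertia, 1)
    km = KMeans(n_clusters=k, n_init=25, random_state=seed).fit(X)
    labels = pd.Series(km.labels_ + 1, index=index, name="cluster")
    return ClusterAssignment(labels, km.cluster_centers_, float(km.inertia_), k)


@dataclass
class CorrelationNetwork:
    """Thresholded gene–gene correlation edges for one cell group."""

    group: str
    edges: pd.DataFrame  # columns gene_a, gene_b, r
    threshold: float
    n_genes_used: int

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _pairwise_detected_corr(
    X: np.ndarray, detected: np.ndarray, min_n: int
) -> np.ndarray:
    """Pearson r per gene pair over cells where both genes are detected.

    Pairs with fewer than ``min_n`` jointly detected cells, or with a
    degenerate variance, get r = 0 (no edge).
    """
    D = detected.astype(float)
    A = np.where(detected, X, 0.0)
    n = D.T @ D
    sx = A.T @ D  # sum of gene-a values over the joint mask (rows: a)
    sy = sx.T
    sxx = (A**2).T @ D
    syy = sxx.T
    sxy = A.T @ A
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        va = sxx - sx**2 / n
        vb = syy - sy**2 / n
        r = cov / np.sqrt(va * vb)
    r = np.nan_to_num(r, nan=0.0, posinf=0.0, neginf=0.0)
    r[n < min_n] = 0.0
    return np.clip(r, -1.0, 1.0)


def correlation_burst(
    matrix: ExpressionMatrix,
    groups: pd.Series | None = None,
    threshold: float = 0.8,
    min_detected: int = 10,
    *,
    absolute: bool = False,
    min_cells: int = 10,
    observations: str = "detected",
) -> dict[str, CorrelationNetwork]:
    """Count strongly correlated gene pairs per cell group.

    Genes detected (above the floor) in fewer than ``min_detected`` cells
    of a group are excluded — a floor-dominated, near-constant gene yields
    spurious r.  With ``observations='detected'`` (default) each pair's
    Pearson r is computed over the cells where *both* genes are detected
    (floor-assigned sentinels are censored non-measurements, and a single
    one would otherwise mask a genuine edge); pairs with fewer than
    ``min_detected`` jointly detected cells carry no edge.
    ``observations='all'`` uses every cell, floors included, instead.

    Edges are gene pairs with ``r > threshold`` (signed by default;
    ``absolute=True`` thresholds |r|).  Groups smaller than ``min_cells``
    are skipped with a warning.  The per-group edge count is the
    transition indicator.
    """
    if observations not in ("detected", "all"):
        raise ValueError(f"unknown observations mode {observations!r}")
    if groups is None:
        groups = pd.Series("all", index=matrix.cells)
    groups = pd.Series(groups).reindex(matrix.cells)
    out: dict[str, CorrelationNetwork] = {}
    for name, cells in groups.groupby(groups).groups.items():
        sub = matrix.values.loc[cells]
        if len(sub) < min_cells:
            warnings.warn(
                f"group {name!r} has {len(sub)} cells (< {min_cells}); skipped",
                stacklevel=2,
            )
            continue
        det = sub.to_numpy(float) > matrix.floor
        used = sub.loc[:, det.sum(axis=0) >= min_detected]
        genes = used.columns
        if len(genes) < 2:
            out[str(name)] = CorrelationNetwork(
                str(name),
                pd.DataFrame(columns=["gene_a", "gene_b", "r"]),
                threshold,
                len(genes),
            )
            continue
        X = used.to_numpy(float)
        if observations == "detected":
            corr = _pairwise_detected_corr(X, X > matrix.floor, min_detected)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.corrcoef(X, rowvar=False)
            corr = np.nan_to_num(corr, nan=0.0)
        stat = np.abs(corr) if absolute else corr
        iu, ju = np.triu_indices(len(genes), k=1)
        keep = stat[iu, ju] > threshold
        edges = pd.DataFrame(
            {
                "gene_a": genes[iu[keep]],
                "gene_b": genes[ju[keep]],
                "r": corr[iu[keep], ju[keep]],
            }
        )
        out[str(name)] = CorrelationNetwork(str(name), edges, threshold, len(genes))
    return out


def pca_contributions(matrix, n_top: int = 40, n_components: int = 2) -> dict[int, pd.Series]:
    """Ranked per-gene contributions (squared loadings) per component.

    Contributions are normalised to sum to 1 within each component; the
    top ``n_top`` genes are returned per component (1-based keys).
    """
    if isinstance(matrix, ExpressionMatrix):
        values = matrix.values
    else:
        values = pd.DataFrame(matrix)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 genes for PCA")
    n_components = min(n_components, *values.shape)
    pca = PCA(n_components=n_components)
    pca.fit(values.to_numpy(float))
    out = {}
    for i, comp in enumerate(pca.components_, start=1):
        contrib = pd.Series(comp**2, index=values.columns)
        contrib /= contrib.sum()
        out[i] = contrib.sort_values(ascending=False).head(n_top)
    return out


def embed_2d(
    matrix,
    method: str = "tsne",
    perplexity: float = 30.0,
    seed: int | None = 0,
) -> pd.DataFrame:
    """2-D embedding for visualisation (t-SNE by default, PCA optional)."""
    X, index = _as_array(matrix)
    if len(X) < 5:
        raise ValueError("need at least 5 cells to embed")
    if method == "tsne":
        if perplexity >= len(X):
            raise ValueError(
                f"perplexity ({perplexity}) must be below the number of cells ({len(X)})"
            )
        coords = TSNE(
            n_components=2,
            perplexity=perplexity,
            random_state=seed,
            init="pca",
        ).fit_transform(X)
    elif method == "pca":
        coords = PCA(n_components=2, random_state=seed).fit_transform(X)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(coords, index=index, columns=["dim1", "dim2"])
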