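"""Sample and peak clustering plus low-dimensional embeddings.

Samples are clustered hierarchically (Ward linkage on Euclidean distances over
peak dimensions, the squared-Euclidean "Ward.D2" objective). Atlas peaks are
clustered by k-means (Lloyd + k-means++, best of several restarts) into open
chromatin region (OCR) clusters; the default k = 15 follows the regional-
atlas design this pipeline implements. Embeddings expose PCA, t-SNE
(perplexity 5) and UMAP (n_neighbors 7, n_components 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

DEFAULT_K = 15


@dataclass
class SampleDendrogram:
    """Ward merge tree over samples; ``linkage_matrix`` is in scipy format."""

    sample_ids: list[str]
    linkage_matrix: np.ndarray

    def cut(self, k: int) -> pd.Series:
        labels = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids, name="cluster")


@dataclass
class OCRClusterAssignment:
    """peak_id -> cluster label in 1..k, labels ordered by descending size."""

    labels: pd.Series
    k: int
    seed: int
    wcss: float

    def peaks_in(self, cluster: int) -> list[str]:
        return self.labels.index[self.labels == cluster].tolist()


def _check_finite(matrix: pd.DataFrame) -> None:
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))
        cells = [(matrix.index[i], matrix.columns[j]) for i, j in bad[:10]]
        raise ValueError(f"non-finite values in matrix at cells {cells}")


def cluster_samples(normalized: pd.DataFrame) -> SampleDendrogram:
    """Ward hierarchical clustering of samples (columns of the normalized matrix)."""
    if normalized.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    _check_finite(normalized)
    X = normalized.to_numpy(dtype=float).T  # samples x peaks
    Z = linkage(X, method="ward")
    return SampleDendrogram(sample_ids=list(normalized.columns), linkage_matrix=Z)


def cluster_peaks(
    normalized: pd.DataFrame,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_restarts: int = 10,
) -> OCRClusterAssignment:
    """k-means OCR clustering of atlas peaks (rows of the normalized matrix).

    Best of ``n_restarts`` k-means++ initializations by within-cluster sum of
    squares; deterministic for a fixed seed. Labels are relabeled 1..k by
    descending cluster size so that label identity is stable across runs.
    """
    if k > normalized.shape[0]:
        raise ValueError(f"k={k} exceeds number of peaks {normalized.shape[0]}")
    _check_finite(normalized)
    X = normalized.to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(X)
    order = np.argsort(-np.bincount(raw, minlength=k), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = pd.Series(relabel[raw], index=normalized.index, name="ocr_cluster")
    return OCRClusterAssignment(labels=labels, k=k, seed=seed, wcss=float(km.inertia_))


def embed(
    normalized: pd.DataFrame,
    method: str = "pca",
    seed: int = 0,
    perplexity: float = 5.0,
    n_neighbors: int = 7,
    n_components: int = 2,
) -> pd.DataFrame:
    """Samples x 2 embedding of the normalized accessibility profiles."""
    _check_finite(normalized)
    X = normalized.to_numpy(dtype=float).T  # samples x peaks
    n = X.shape[0]
    if method == "pca":
        coords = PCA(n_components=n_components, random_state=seed).fit_transform(X)
    elif method == "tsne":
        if perplexity >= (n - 1) / 3:
            raise ValueError(
                f"perplexity {perplexity} requires > {int(3 * perplexity) + 1} "
                f"samples, got {n}"
            )
        coords = TSNE(
            n_components=n_components, perplexity=perplexity, random_state=seed,
            init="pca",
        ).fit_transform(X)
    elif method == "umap":
        import umap  # deferred: numba-compiled import is slow

        coords = umap.UMAP(
            n_neighbors=n_neighbors, n_components=n_components, random_state=seed,
        ).fit_transform(X)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(
        coords[:, :n_components],
        index=normalized.columns,
        columns=[f"dim{i + 1}" for i in range(n_components)],
    )
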