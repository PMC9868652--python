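"""Cluster-purity scoring of learned embeddings.

Embeddings are clustered with a Gaussian mixture model initialized from
K-means centroids; purity of the case/control labels within the clusters
is scored by the size-weighted total entropy

    H = sum_i w_i * sum_j -(n_ij / n_i) * ln(n_ij / n_i),   w_i = n_i / N,

which is 0 iff every cluster is class-pure and bounded by ln(#classes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.mixture import GaussianMixture

__all__ = [
    "ClusterContingency",
    "cluster_embeddings",
    "contingency_from_labels",
    "total_entropy",
    "tsne_projection",
]

logger = logging.getLogger(__name__)


@dataclass
class ClusterContingency:
    """Cluster-by-class counts ``n_ij`` (rows: clusters, cols: classes)."""

    n_ij: np.ndarray

    def __post_init__(self) -> None:
        self.n_ij = np.asarray(self.n_ij, dtype=float)
        if self.n_ij.ndim != 2 or self.n_ij.size == 0:
            raise ValueError("contingency must be a non-empty 2-D count table")
        if (self.n_ij < 0).any():
            raise ValueError("counts must be >= 0")

    @property
    def n_i(self) -> np.ndarray:
        return self.n_ij.sum(axis=1)

    @property
    def N(self) -> float:
        return float(self.n_ij.sum())


def contingency_from_labels(
    cluster_labels: np.ndarray, class_labels: np.ndarray
) -> ClusterContingency:
    clusters = np.unique(cluster_labels)
    classes = np.unique(class_labels)
    table = np.zeros((len(clusters), len(classes)))
    for i, c in enumerate(clusters):
        for j, k in enumerate(classes):
            table[i, j] = np.sum((cluster_labels == c) & (class_labels == k))
    return ClusterContingency(table)


def total_entropy(
    contingency: ClusterContingency, weighting: str = "cluster_size"
) -> float:
    """Size-weighted total entropy of a clustering (natural log).

    ``weighting="cluster_size"`` uses ``w_ij = n_i / N`` (the standard
    convention; bounded by ln of the class count). ``"per_class"`` uses
    ``w_ij = n_ij / N``. Empty clusters are skipped and ``0·ln 0 = 0``.
    """
    if weighting not in ("cluster_size", "per_class"):
        raise ValueError(f"unknown weighting {weighting!r}")
    n_ij = contingency.n_ij
    n_i = contingency.n_i
    N = contingency.N
    if N == 0:
        raise ValueError("empty contingency table")
    total = 0.0
    for i in range(n_ij.shape[0]):
        if n_i[i] == 0:
            continue
        p = n_ij[i] / n_i[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        if weighting == "cluster_size":
            w = n_i[i] / N
            total += float(-plogp.sum() * w)
        else:
            w_ij = n_ij[i] / N
            total += float(-(plogp * w_ij).sum())
    return total


def cluster_embeddings(
    embeddings: np.ndarray,
    n_components: int = 2,
    seed: int = 0,
    max_retries: int = 5,
) -> np.ndarray:
    """Hard cluster assignments from a K-means-initialized Gaussian
    mixture fit to convergence (maximum responsibility decides)."""
    E = np.atleast_2d(np.asarray(embeddings, dtype=float))
    if E.shape[0] < E.shape[1] and E.shape[0] == 1:
        E = E.T
    n = E.shape[0]
    if n_components < 1 or n < n_components:
        raise ValueError("need n_components >= 1 and at least that many points")
    for attempt in range(max_retries):
        s = seed + attempt
        km = KMeans(n_clusters=n_components, n_init=10, random_state=s).fit(E)
        gm = GaussianMixture(
            n_components=n_components, means_init=km.cluster_centers_,
            random_state=s, reg_covar=1e-6,
        ).fit(E)
        labels = gm.predict(E)
        if len(np.unique(labels)) == n_components or n_components == 1:
            return labels
        logger.warning("degenerate mixture component on attempt %d; retrying",
                       attempt + 1)
    raise RuntimeError("GMM clustering repeatedly produced empty components")


def tsne_projection(embeddings: np.ndarray, seed: int = 0) -> np.ndarray:
    """2-D t-SNE map of the embeddings (figures only; never feeds the
    entropy score). Deterministic under the seed."""
    E = np.atleast_2d(np.asarray(embeddings, dtype=float))
    if E.shape[0] < 5:
        raise ValueError("need at least 5 patients for a t-SNE map")
    perplexity = min(30.0, (E.shape[0] - 1) / 3.0)
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
                init="pca")
    return tsne.fit_transform(E)
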