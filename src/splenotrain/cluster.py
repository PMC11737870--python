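"""PCA embedding, Euclidean KNN graph, Louvain clustering, and marker-based
cluster annotation."""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import igraph as ig
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .preprocess import ExpressionMatrix

__all__ = [
    "Embedding",
    "KNNGraph",
    "Clustering",
    "run_pca",
    "build_knn_graph",
    "louvain_cluster",
    "annotate_clusters",
]


@dataclass
class Embedding:
    """PCA embedding: observation coordinates plus feature loadings.

    Components are sign-fixed so the largest-magnitude loading of each
    component is positive, making the decomposition deterministic.
    """

    coordinates: np.ndarray  # observations x components
    component_loadings: np.ndarray  # features x components
    explained_variance_fraction: np.ndarray
    obs_ids: list[str]
    feature_ids: list[str]
    feature_means: np.ndarray  # centering record

    def __post_init__(self) -> None:
        n_comp = self.coordinates.shape[1]
        if self.component_loadings.shape != (len(self.feature_ids), n_comp):
            raise ValueError("loading matrix shape mismatch")
        ortho = self.component_loadings.T @ self.component_loadings
        if not np.allclose(ortho, np.eye(n_comp), atol=1e-8):
            raise ValueError("components are not orthonormal")
        if (np.diff(self.explained_variance_fraction) > 1e-12).any():
            raise ValueError("explained variance must be non-increasing")


@dataclass
class KNNGraph:
    nodes: list[str]
    edges: set[tuple[int, int]]  # index pairs (i < j), unit weight
    k: int

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-edge in KNN graph")
        deg = np.zeros(len(self.nodes), dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        if len(self.nodes) > self.k and (deg < self.k).any():
            raise ValueError("union-of-neighborhoods graph must have degree >= k")

    def degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.nodes), dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


@dataclass
class Clustering:
    label_of: dict[str, int]
    n_clusters: int
    modularity: float
    annotation_of: dict[int, str] | None = None
    marker_scores: pd.DataFrame | None = None  # clusters x types

    def __post_init__(self) -> None:
        if self.n_clusters != len(set(self.label_of.values())):
            raise ValueError("n_clusters disagrees with the label map")

    def labels(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self.label_of[c] for c in ids])

    def annotations(self, ids: Sequence[str]) -> list[str]:
        if self.annotation_of is None:
            raise ValueError("clustering has not been annotated")
        return [self.annotation_of[self.label_of[c]] for c in ids]


def _pca_embed(X: np.ndarray, n_pcs: int, obs_ids: list[str],
               feature_ids: list[str]) -> Embedding:
    max_pcs = min(X.shape[0] - 1, X.shape[1])  # centering costs one observation dof
    if n_pcs < 1 or n_pcs > max_pcs:
        raise ValueError(f"n_pcs must lie in [1, {max_pcs}]; got {n_pcs}")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("zero variance: constant matrix has no principal components")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    coords = pca.fit_transform(X)
    loadings = pca.components_.T  # features x components
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(n_pcs):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            coords[:, j] *= -1.0
    return Embedding(
        coordinates=coords,
        component_loadings=loadings,
        explained_variance_fraction=pca.explained_variance_ratio_,
        obs_ids=obs_ids,
        feature_ids=feature_ids,
        feature_means=pca.mean_,
    )


def run_pca(expr: ExpressionMatrix, n_pcs: int = 40,
            genes: Sequence[str] | None = None) -> Embedding:
    """Gene-centered PCA of cells; optionally restricted to ``genes``
    (typically the variable-gene list).  Features are centered but not
    variance-scaled."""
    if genes is not None:
        expr = expr.restrict_genes(genes)
    X = expr.values.T  # cells x genes
    return _pca_embed(X, n_pcs, obs_ids=list(expr.column_ids),
                      feature_ids=list(expr.gene_ids))


def build_knn_graph(emb: Embedding, k: int = 20) -> KNNGraph:
    """Undirected unit-weight KNN graph in the embedding (Euclidean).

    Each cell is linked to its ``k`` nearest others; the graph is
    symmetrized by edge union, so degrees are >= k.  Distance ties break by
    cell index order.
    """
    X = emb.coordinates
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    dist = cdist(X, X)
    edges: set[tuple[int, int]] = set()
    idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((idx, dist[i]))  # distance, then cell index
        neighbors = [j for j in order if j != i][:k]
        for j in neighbors:
            edges.add((i, j) if i < j else (j, i))
    return KNNGraph(nodes=list(emb.obs_ids), edges=edges, k=k)


def louvain_cluster(graph: KNNGraph, resolution: float = 1.0,
                    seed: int = 0) -> Clustering:
    """Louvain modularity optimization on the KNN graph.

    Reproducible given (graph, resolution, seed); disconnected graphs are
    allowed and isolated nodes form their own communities.
    """
    n = len(graph.nodes)
    if n == 0:
        raise ValueError("empty graph")
    ig.set_random_number_generator(random.Random(seed))
    g = ig.Graph(n=n, edges=sorted(graph.edges))
    part = g.community_multilevel(resolution=resolution)
    membership = part.membership
    label_of = {node: int(m) for node, m in zip(graph.nodes, membership)}
    modularity = float(g.modularity(membership, resolution=resolution)) if g.ecount() else 0.0
    return Clustering(label_of=label_of, n_clusters=len(set(membership)),
                      modularity=modularity)


def annotate_clusters(clust: Clustering, expr: ExpressionMatrix,
                      markers: Mapping[str, Sequence[str]]) -> Clustering:
    """Annotate clusters by marker-panel mean expression.

    For each cluster and candidate type, the mean expression of the type's
    markers is computed and z-scored across clusters; each cluster is
    assigned the argmax type.  Exact ties and all-zero clusters are labeled
    ``"ambiguous"``.  With a single cluster, raw means are compared (the
    z-score is degenerate).  Types with no marker present in the matrix are
    dropped with a warning; if no marker of any type is present an error is
    raised.
    """
    present: dict[str, list[str]] = {}
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    for t, genes in markers.items():
        found = [g for g in genes if g in gene_pos]
        if found:
            present[t] = found
        else:
            warnings.warn(f"no marker of type {t!r} present in the matrix; type dropped")
    if not present:
        raise ValueError("no marker genes found in the expression matrix")
    cluster_ids = sorted(set(clust.label_of.values()))
    cell_labels = np.array([clust.label_of[c] for c in expr.column_ids])
    raw = pd.DataFrame(index=cluster_ids, columns=list(present), dtype=float)
    for cl in cluster_ids:
        cells = cell_labels == cl
        if not cells.any():
            raise ValueError(f"cluster {cl} has no cells in the expression matrix")
        for t, genes in present.items():
            rows = [gene_pos[g] for g in genes]
            raw.loc[cl, t] = float(expr.values[np.ix_(rows, np.flatnonzero(cells))].mean())
    if len(cluster_ids) > 1:
        sd = raw.std(axis=0, ddof=0)
        scores = (raw - raw.mean(axis=0)) / sd.replace(0.0, np.nan)
        scores = scores.fillna(0.0)
    else:
        scores = raw  # degenerate z-score: compare raw means
    annotation: dict[int, str] = {}
    zero_expr = raw.sum(axis=1) == 0
    for cl in cluster_ids:
        row = scores.loc[cl]
        best = row.max()
        winners = list(row.index[row == best])
        if zero_expr.loc[cl] or len(winners) > 1:
            annotation[cl] = "ambiguous"
        else:
            annotation[cl] = winners[0]
    return Clustering(label_of=dict(clust.label_of), n_clusters=clust.n_clusters,
                      modularity=clust.modularity, annotation_of=annotation,
                      marker_scores=scores)
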