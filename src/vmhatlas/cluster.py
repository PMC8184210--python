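"""PCA with elbow retention, SNN graph, modularity clustering, and the
two-phase silhouette-maximizing parameter search.

The search mirrors how the cluster granularity was tuned: first the
neighbor count of the SNN graph is varied from 10 up to sqrt(n_cells) at
resolution 1 and the mean silhouette width picks the winner; then the
resolution is stepped up from 0.2 in increments of 0.2 until the
silhouette has peaked, and the argmax is returned.  Clusters are finally
ordered by an average-linkage hierarchy over their centroids in PC space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
from scipy.cluster.hierarchy import dendrogram, linkage
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import NearestNeighbors


@dataclass
class EmbeddingResult:
    scores: np.ndarray  # cells x PCs
    loadings: np.ndarray  # genes x PCs
    variance_explained: np.ndarray
    n_retained: int

    @property
    def retained(self) -> np.ndarray:
        return self.scores[:, : self.n_retained]


@dataclass
class ClusterSolution:
    labels: np.ndarray
    n_neighbors: int
    resolution: float
    mean_silhouette: float
    k: int
    trace: list[tuple] = field(default_factory=list)  # (phase, param, silhouette)


def elbow_index(variance: np.ndarray) -> int:
    """Index of max perpendicular distance from the scree curve to the
    chord joining its first and last points (0-based; ties -> smallest)."""
    v = np.asarray(variance, dtype=float)
    n = len(v)
    if n < 3:
        return 0
    x = np.arange(n, dtype=float)
    p0 = np.array([x[0], v[0]])
    p1 = np.array([x[-1], v[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        return 0
    # perpendicular distance of each scree point to the chord
    d = np.abs(chord[0] * (v - p0[1]) - chord[1] * (x - p0[0])) / norm
    return int(np.argmax(d))


def pca_elbow(scaled: np.ndarray, max_pcs: int = 50,
              min_pcs: int = 5, seed: int = 0) -> EmbeddingResult:
    """PCA of a cells-ready (genes x cells) scaled matrix; retain PCs at the
    scree-plot elbow, clipped to [min_pcs, max_pcs]."""
    X = np.asarray(scaled, dtype=float).T  # cells x genes
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 cells and >= 2 genes")
    if not np.any(X.std(axis=0) > 0):
        raise ValueError("zero-variance input")
    n_comp = min(max_pcs, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="randomized",
              random_state=int(seed) % (2**31))
    scores = pca.fit_transform(X)
    var = pca.explained_variance_
    n_retained = int(np.clip(elbow_index(var) + 1, min(min_pcs, n_comp), n_comp))
    return EmbeddingResult(scores=scores, loadings=pca.components_.T,
                           variance_explained=var, n_retained=n_retained)


def snn_graph(scores: np.ndarray, n_neighbors: int,
              prune: float = 1.0 / 15) -> ig.Graph:
    """Shared-nearest-neighbor graph: edge weight = Jaccard overlap of the
    two cells' kNN sets (self included); weights < prune dropped."""
    if n_neighbors <= 0:
        raise ValueError("n_neighbors must be positive")
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    if n_neighbors >= n:
        raise ValueError("n_neighbors must be < n_cells")
    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(X)
    idx = nn.kneighbors(return_distance=False)
    knn = np.concatenate([np.arange(n)[:, None], idx[:, : n_neighbors - 1]], axis=1)

    # sparse membership matrix -> pairwise intersection sizes
    import scipy.sparse as sp
    rows = np.repeat(np.arange(n), knn.shape[1])
    M = sp.csr_matrix((np.ones(rows.size), (rows, knn.ravel())), shape=(n, n))
    inter = (M @ M.T).tocoo()
    k = knn.shape[1]
    mask = inter.row < inter.col
    r, c, common = inter.row[mask], inter.col[mask], inter.data[mask]
    jacc = common / (2 * k - common)
    keep = jacc >= prune
    edges = list(zip(r[keep].tolist(), c[keep].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = jacc[keep].tolist()
    return g


def modularity_cluster(graph: ig.Graph, resolution: float = 1.0,
                       seed: int = 0) -> np.ndarray:
    """Leiden modularity clustering (RB configuration model) with a
    resolution parameter; deterministic under seed."""
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        weights="weight" if "weight" in graph.es.attributes() else None,
        resolution_parameter=resolution, seed=int(seed) % (2**31),
        n_iterations=2,
    )
    labels = np.asarray(part.membership)
    # renumber contiguously by first appearance
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def mean_silhouette(scores: np.ndarray, labels: np.ndarray,
                    subsample: int = 5000, seed: int = 0) -> float:
    """Mean silhouette width in retained-PC space (Euclidean).

    Cells in singleton clusters contribute 0.  When n_cells exceeds
    ``subsample``, a seeded subsample is used; otherwise the value is exact.
    """
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    n = X.shape[0]
    if n > subsample:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=subsample, replace=False)
        X, labels = X[idx], labels[idx]
        if len(np.unique(labels)) < 2:
            raise ValueError("subsample lost all but one cluster")
    counts = {int(l): int((labels == l).sum()) for l in np.unique(labels)}
    if all(v == 1 for v in counts.values()):
        return 0.0
    # all points identical -> 0/0 convention -> 0
    if np.all(X == X[0]):
        return 0.0
    sil = silhouette_samples(X, labels)
    sizes = np.array([counts[int(l)] for l in labels])
    sil[sizes == 1] = 0.0
    return float(np.nan_to_num(sil, nan=0.0).mean())


def optimize_clustering(scores: np.ndarray, seed: int = 0,
                        prune: float = 1.0 / 15,
                        resolution_step: float = 0.2,
                        max_resolution: float = 3.0,
                        search_subsample: int = 3000) -> ClusterSolution:
    """Two-phase silhouette-maximizing search over (n_neighbors, resolution).

    Phase 1 holds resolution at 1.0 and varies n_neighbors from 10 to
    sqrt(n_cells) (strided to <= 9 candidates); phase 2 fixes the winning
    neighbor count and steps resolution from 0.2 upward by 0.2 until the
    silhouette has decreased on two consecutive steps (hard cap 3.0),
    returning the argmax over everything evaluated.
    """
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    if n < 20:
        raise ValueError("need >= 20 cells")
    rng = np.random.default_rng(seed)
    sil_seed = int(rng.integers(2**31))

    hi = int(np.floor(np.sqrt(n)))
    if hi <= 10:
        grid = [min(10, n - 1)]
    else:
        stride = max(1, (hi - 10) // 8)
        grid = list(range(10, hi + 1, stride))

    def evaluate(n_nb: int, res: float, subsample: int):
        g = snn_graph(X, n_nb, prune=prune)
        labels = modularity_cluster(g, resolution=res, seed=seed)
        if len(np.unique(labels)) < 2:
            return labels, -1.0
        s = mean_silhouette(X, labels, subsample=subsample, seed=sil_seed)
        return labels, s

    trace: list[tuple] = []
    best = None  # (sil, labels, n_nb, res)
    for n_nb in grid:
        labels, s = evaluate(n_nb, 1.0, search_subsample)
        trace.append(("neighbors", n_nb, s))
        if best is None or s > best[0]:
            best = (s, labels, n_nb, 1.0)

    n_nb = best[2]
    decreases = 0
    prev = -np.inf
    res = resolution_step
    while res <= max_resolution + 1e-9:
        labels, s = evaluate(n_nb, res, search_subsample)
        trace.append(("resolution", res, s))
        if s > best[0]:
            best = (s, labels, n_nb, res)
        decreases = decreases + 1 if s < prev else 0
        if decreases >= 2:
            break
        prev = s
        res = round(res + resolution_step, 10)

    s_best, labels, n_nb, res = best
    _, labels = np.unique(labels, return_inverse=True)
    k = int(labels.max()) + 1
    return ClusterSolution(labels=labels, n_neighbors=int(n_nb),
                           resolution=float(res),
                           mean_silhouette=float(s_best), k=k, trace=trace)


def order_clusters(scores: np.ndarray, labels: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Renumber clusters by leaf order of an average-linkage hierarchy over
    their centroids in retained-PC space.

    Returns (new_labels, linkage_matrix).  Deterministic: ties follow the
    original label order.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 clusters to order")
    centroids = np.vstack([scores[labels == l].mean(axis=0) for l in uniq])
    Z = linkage(centroids, method="average")
    leaf_order = dendrogram(Z, no_plot=True)["leaves"]
    mapping = {int(uniq[old]): new for new, old in enumerate(leaf_order)}
    new_labels = np.array([mapping[int(l)] for l in labels])
    return new_labels, Z
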