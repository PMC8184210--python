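"""Clustering primitives: elbow, SNN graph, modularity, silhouette, search."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist, squareform

from vmhatlas import cluster


# ---------------------------------------------------------------- elbow ----
def brute_force_elbow(v):
    v = np.asarray(v, dtype=float)
    x = np.arange(len(v), dtype=float)
    p0, p1 = np.array([x[0], v[0]]), np.array([x[-1], v[-1]])
    chord = p1 - p0
    best, best_d = 0, -1.0
    for i in range(len(v)):
        d = abs(chord[0] * (v[i] - p0[1]) - chord[1] * (x[i] - p0[0]))
        d /= np.hypot(*chord)
        if d > best_d + 1e-12:
            best, best_d = i, d
    return best


@pytest.mark.parametrize("v", [
    [10, 5, 2.5, 1.25] + [0.1] * 20,
    [100, 50, 10, 9, 8, 7, 1, 1, 1],
    list(np.exp(-np.linspace(0, 5, 40))),
])
def test_elbow_matches_brute_force(v):
    assert cluster.elbow_index(v) == brute_force_elbow(v)


def test_elbow_flat_variances_hit_lower_clip():
    emb_in = np.random.default_rng(0).normal(size=(30, 40))
    # all-equal variance vector -> chord distance 0 everywhere -> index 0,
    # clipped up to the minimum retained count
    assert cluster.elbow_index(np.ones(20)) == 0
    res = cluster.pca_elbow(emb_in, min_pcs=5, seed=0)
    assert res.n_retained >= 5


def test_pca_scores_preserve_pairwise_distances():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(20, 40))  # genes x cells; full rank retainable
    res = cluster.pca_elbow(X, max_pcs=20, seed=0)
    d_in = pdist(X.T)
    d_out = pdist(res.scores)
    assert np.allclose(d_in, d_out, atol=1e-8)


def test_pca_rejects_degenerate_input():
    with pytest.raises(ValueError):
        cluster.pca_elbow(np.zeros((10, 20)))


# ------------------------------------------------------------------ SNN ----
def brute_force_snn(X, k):
    n = len(X)
    D = cdist(X, X)
    knn = []
    for i in range(n):
        order = np.argsort(D[i], kind="stable")
        s = {i}
        for j in order:
            if len(s) == k:
                break
            s.add(int(j))
        knn.append(s)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(knn[i] & knn[j])
            W[i, j] = W[j, i] = inter / (2 * k - inter)
    return W


def test_snn_hand_instance_matches_brute_force():
    X = np.array([[0.0, 0], [0.1, 0], [0.2, 0], [5.0, 0], [5.1, 0], [5.2, 0]])
    k = 3
    g = cluster.snn_graph(X, n_neighbors=k, prune=0.0)
    W = brute_force_snn(X, k)
    got = np.zeros((6, 6))
    for e, w in zip(g.get_edgelist(), g.es["weight"]):
        got[e[0], e[1]] = got[e[1], e[0]] = w
    assert np.allclose(got, W)


def test_snn_identical_and_disjoint_neighborhoods():
    X = np.array([[0.0, 0], [0.1, 0], [0.2, 0], [9.0, 0], [9.1, 0], [9.2, 0]])
    g = cluster.snn_graph(X, n_neighbors=3, prune=1.0 / 15)
    W = {}
    for e, w in zip(g.get_edgelist(), g.es["weight"]):
        W[tuple(sorted(e))] = w
    assert W[(0, 1)] == 1.0  # identical kNN sets
    assert (0, 3) not in W  # disjoint kNN sets
    assert all(1.0 / 15 <= w <= 1.0 for w in g.es["weight"])


def test_snn_rejects_bad_neighbors():
    X = np.zeros((5, 2))
    with pytest.raises(ValueError):
        cluster.snn_graph(X, n_neighbors=0)
    with pytest.raises(ValueError):
        cluster.snn_graph(X, n_neighbors=5)


# ------------------------------------------------------------ modularity ----
def test_modularity_two_cliques():
    import igraph as ig
    g = ig.Graph.Full(5) + ig.Graph.Full(5)
    g.es["weight"] = [1.0] * g.ecount()
    labels = cluster.modularity_cluster(g, resolution=1.0, seed=0)
    assert len(np.unique(labels)) == 2
    assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1


def test_modularity_deterministic_under_seed():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(200, 5))
    g = cluster.snn_graph(X, n_neighbors=10)
    l1 = cluster.modularity_cluster(g, resolution=1.0, seed=3)
    l2 = cluster.modularity_cluster(g, resolution=1.0, seed=3)
    assert np.array_equal(l1, l2)


def test_resolution_increases_cluster_count_on_average():
    rng = np.random.default_rng(1)
    X = np.concatenate([rng.normal(loc=c, scale=0.5, size=(80, 4))
                        for c in (0, 4, 8)])
    g = cluster.snn_graph(X, n_neighbors=12)
    lo = np.mean([len(np.unique(cluster.modularity_cluster(g, 0.3, seed=s)))
                  for s in range(5)])
    hi = np.mean([len(np.unique(cluster.modularity_cluster(g, 3.0, seed=s)))
                  for s in range(5)])
    assert hi >= lo


# ------------------------------------------------------------- silhouette ----
def brute_force_silhouette(X, labels):
    D = squareform(pdist(X))
    n = len(X)
    vals = []
    for i in range(n):
        same = (labels == labels[i])
        if same.sum() == 1:
            vals.append(0.0)
            continue
        a = D[i, same].sum() / (same.sum() - 1)
        b = min(D[i, labels == l].mean()
                for l in np.unique(labels) if l != labels[i])
        vals.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(vals))


def test_silhouette_hand_case_two_tight_pairs():
    X = np.array([[0.0], [0.1], [10.0], [10.1]])
    labels = np.array([0, 0, 1, 1])
    s = cluster.mean_silhouette(X, labels)
    assert s == pytest.approx(0.98999975, abs=1e-6)


def test_silhouette_identical_points_convention():
    X = np.zeros((10, 3))
    labels = np.array([0] * 5 + [1] * 5)
    assert cluster.mean_silhouette(X, labels) == 0.0


@pytest.mark.parametrize("seed", range(3))
def test_silhouette_matches_brute_force_exactly(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(200, 4))
    labels = rng.integers(0, 3, size=200)
    got = cluster.mean_silhouette(X, labels, subsample=200)
    assert got == pytest.approx(brute_force_silhouette(X, labels), abs=1e-12)


def test_silhouette_requires_two_clusters():
    with pytest.raises(ValueError):
        cluster.mean_silhouette(np.zeros((5, 2)), np.zeros(5))


# --------------------------------------------------------------- search ----
def test_optimize_two_separated_blobs():
    rng = np.random.default_rng(2)
    X = np.concatenate([rng.normal(0, 0.3, size=(200, 4)),
                        rng.normal(20, 0.3, size=(200, 4))])
    sol = cluster.optimize_clustering(X, seed=0)
    assert sol.k == 2
    assert sol.mean_silhouette > 0.8


def test_optimize_deterministic():
    rng = np.random.default_rng(3)
    X = np.concatenate([rng.normal(c, 0.5, size=(60, 3)) for c in (0, 5, 10)])
    s1 = cluster.optimize_clustering(X, seed=9)
    s2 = cluster.optimize_clustering(X, seed=9)
    assert np.array_equal(s1.labels, s2.labels)
    assert s1.n_neighbors == s2.n_neighbors
    assert s1.resolution == s2.resolution


def test_optimize_returns_trace_argmax():
    """The returned silhouette is >= every evaluated candidate's score."""
    rng = np.random.default_rng(4)
    X = np.concatenate([rng.normal(c, 0.6, size=(80, 3)) for c in (0, 4, 9)])
    sol = cluster.optimize_clustering(X, seed=1)
    evaluated = [s for _, _, s in sol.trace]
    assert sol.mean_silhouette >= max(evaluated) - 1e-12


# -------------------------------------------------------------- ordering ----
def test_order_clusters_is_bijection_and_keeps_neighbors_adjacent():
    rng = np.random.default_rng(5)
    centers = {0: 0.0, 1: 1.0, 2: 10.0, 3: 11.0}
    X = np.concatenate([rng.normal(c, 0.01, size=(20, 1))
                        for c in centers.values()])
    labels = np.repeat([2, 0, 3, 1], 20)  # scrambled original labels
    new_labels, Z = cluster.order_clusters(X, labels)
    assert set(new_labels) == {0, 1, 2, 3}
    # centroids at 0 and 1 must be adjacent in the leaf order, as must 10/11
    order = []
    for l in new_labels:
        if l not in order:
            order.append(l)
    centroid_of = {l: X[new_labels == l].mean() for l in set(new_labels)}
    leaf_vals = [centroid_of[l] for l in sorted(set(new_labels))]
    near = sorted(range(4), key=lambda l: leaf_vals[l])[:2]
    assert abs(near[0] - near[1]) == 1
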