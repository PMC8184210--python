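"""Ortholog-restricted cross-species comparison and label transfer.

Three layers: (1) a pairwise Pearson correlation map of per-cluster mean
scaled profiles over the genes called variable in both datasets; (2) a
reduced anchor algorithm — canonical-correlation embedding via SVD of the
cross-product of the two scaled matrices, mutual-nearest-neighbor anchor
pairs scored by shared-neighborhood overlap, and score-weighted voting to
transfer reference labels onto query cells; (3) an integration step that
corrects query (species B) expression toward the reference by
anchor-weighted difference vectors before joint clustering.  Species A is
always the fixed reference and is never altered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from . import cluster as _cluster
from .containers import ExpressionMatrix, NormalizedMatrix


@dataclass
class OrthologMap:
    """1:1 gene pairs (gene_A, gene_B); neither side may repeat."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("empty ortholog map")
        a = [p[0] for p in self.pairs]
        b = [p[1] for p in self.pairs]
        if len(set(a)) != len(a) or len(set(b)) != len(b):
            raise ValueError("ortholog map is not 1:1")

    @classmethod
    def from_dict(cls, d: dict[str, str]) -> "OrthologMap":
        return cls(pairs=sorted(d.items()))

    def b_to_a(self) -> dict[str, str]:
        return {b: a for a, b in self.pairs}


@dataclass
class TransferResult:
    predicted_label: np.ndarray
    confidence: np.ndarray
    anchors: list[tuple[int, int, float]]  # (cell_A idx, cell_B idx, score)


def apply_ortholog_map(matrix_b: ExpressionMatrix, omap: OrthologMap,
                       matrix_a: ExpressionMatrix | None = None
                       ) -> ExpressionMatrix:
    """Rename species-B genes into the species-A namespace.

    Unmapped genes are dropped; genes not expressed (all-zero) in B — and,
    when ``matrix_a`` is given, in A — are dropped too.
    """
    b2a = omap.b_to_a()
    idx, new_ids = [], []
    expr_b = np.asarray((matrix_b.counts > 0).sum(axis=1)).ravel() > 0
    expressed_a = None
    if matrix_a is not None:
        ea = np.asarray((matrix_a.counts > 0).sum(axis=1)).ravel() > 0
        expressed_a = {g for g, e in zip(matrix_a.gene_ids, ea) if e}
    for i, g in enumerate(matrix_b.gene_ids):
        a_name = b2a.get(str(g))
        if a_name is None or not expr_b[i]:
            continue
        if expressed_a is not None and a_name not in expressed_a:
            continue
        idx.append(i)
        new_ids.append(a_name)
    if len(set(new_ids)) != len(new_ids):
        raise ValueError("duplicate target genes after mapping; map not 1:1")
    out = matrix_b.subset_genes(np.array(idx, dtype=int))
    out.gene_ids = np.array(new_ids, dtype=object)
    return out


def correlation_map(norm_a: NormalizedMatrix, labels_a: np.ndarray,
                    norm_b: NormalizedMatrix, labels_b: np.ndarray,
                    var_a: set[str], var_b: set[str],
                    min_genes: int = 10) -> pd.DataFrame:
    """Cluster-by-cluster Pearson correlation of mean scaled profiles over
    the genes variable in both datasets (rows = A clusters, cols = B)."""
    genes = sorted((var_a & var_b) & set(norm_a.gene_ids) & set(norm_b.gene_ids))
    if len(genes) < min_genes:
        raise ValueError(f"only {len(genes)} shared variable genes")
    if norm_a.scaled is None or norm_b.scaled is None:
        raise ValueError("matrices must be scaled first")

    def profiles(norm, labels):
        idx = [norm.gene_index(g) for g in genes]
        sub = norm.scaled[idx, :]
        uniq = np.unique(labels)
        return np.vstack([sub[:, labels == l].mean(axis=1) for l in uniq]), uniq

    pa, ua = profiles(norm_a, np.asarray(labels_a))
    pb, ub = profiles(norm_b, np.asarray(labels_b))
    corr = np.corrcoef(pa, pb)[: len(ua), len(ua):]
    return pd.DataFrame(corr, index=ua, columns=ub)


def _shared_scaled(norm_a: NormalizedMatrix, norm_b: NormalizedMatrix,
                   genes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    ia = [norm_a.gene_index(g) for g in genes]
    ib = [norm_b.gene_index(g) for g in genes]
    return norm_a.scaled[ia, :], norm_b.scaled[ib, :]


def cca_embed(Xa: np.ndarray, Xb: np.ndarray, n_cc: int = 20,
              seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Canonical-correlation embedding: SVD of Xa^T Xb (genes x cells
    inputs); returns L2-normalized per-cell embeddings (cells x n_cc)."""
    from sklearn.utils.extmath import randomized_svd

    K = Xa.T @ Xb  # cells_A x cells_B
    n_cc = min(n_cc, min(K.shape) - 1)
    U, s, Vt = randomized_svd(K, n_components=n_cc,
                              random_state=int(seed) % (2**31))
    emb_a = U / np.maximum(np.linalg.norm(U, axis=1, keepdims=True), 1e-12)
    emb_b = Vt.T / np.maximum(np.linalg.norm(Vt.T, axis=1, keepdims=True), 1e-12)
    return emb_a, emb_b


def find_anchors(emb_a: np.ndarray, emb_b: np.ndarray, k_anchor: int = 5,
                 k_score: int = 30) -> list[tuple[int, int, float]]:
    """Mutual-nearest-neighbor anchor pairs across species in CC space,
    scored in [0, 1] by shared-neighborhood overlap."""
    nn_ab = NearestNeighbors(n_neighbors=min(k_anchor, len(emb_b))).fit(emb_b)
    nn_ba = NearestNeighbors(n_neighbors=min(k_anchor, len(emb_a))).fit(emb_a)
    ab = nn_ab.kneighbors(emb_a, return_distance=False)
    ba = nn_ba.kneighbors(emb_b, return_distance=False)
    ba_sets = [set(row) for row in ba]
    anchors = [(i, int(j)) for i in range(len(emb_a)) for j in ab[i]
               if i in ba_sets[j]]
    if not anchors:
        raise ValueError("no mutual-nearest-neighbor anchors; try larger k_anchor")

    # score: overlap of the two cells' neighborhoods among anchor cells
    ks = min(k_score, len(emb_a), len(emb_b))
    na = NearestNeighbors(n_neighbors=ks).fit(emb_a)
    nb = NearestNeighbors(n_neighbors=ks).fit(emb_b)
    neigh_a = na.kneighbors(emb_a[[a for a, _ in anchors]],
                            return_distance=False)
    neigh_b = nb.kneighbors(emb_b[[b for _, b in anchors]],
                            return_distance=False)
    a_set = {a for a, _ in anchors}
    b_set = {b for _, b in anchors}
    scores = []
    for row_a, row_b in zip(neigh_a, neigh_b):
        overlap = len([x for x in row_a if x in a_set]) + \
            len([x for x in row_b if x in b_set])
        scores.append(overlap / (2.0 * ks))
    smax = max(scores) or 1.0
    return [(int(a), int(b), float(s / smax))
            for (a, b), s in zip(anchors, scores)]


def anchor_transfer(norm_a: NormalizedMatrix, labels_a: np.ndarray,
                    norm_b: NormalizedMatrix, shared_genes: list[str],
                    n_cc: int = 20, k_anchor: int = 5, k_weight: int = 10,
                    seed: int = 0) -> TransferResult:
    """Transfer reference (A) labels onto query (B) cells.

    Each query cell takes a vote over its ``k_weight`` nearest anchors in
    CC space, weighted by anchor score and inverse distance; the predicted
    label is the argmax and the confidence its normalized vote share.
    """
    if len(shared_genes) < n_cc:
        raise ValueError("need >= n_cc shared variable genes")
    Xa, Xb = _shared_scaled(norm_a, norm_b, sorted(shared_genes))
    emb_a, emb_b = cca_embed(Xa, Xb, n_cc=n_cc, seed=seed)
    anchors = find_anchors(emb_a, emb_b, k_anchor=k_anchor)

    labels_a = np.asarray(labels_a)
    anchor_b = np.array([b for _, b, _ in anchors])
    anchor_lab = np.array([labels_a[a] for a, _, _ in anchors])
    anchor_score = np.array([s for _, _, s in anchors])

    kw = min(k_weight, len(anchors))
    nn = NearestNeighbors(n_neighbors=kw).fit(emb_b[anchor_b])
    dist, idx = nn.kneighbors(emb_b)
    w = anchor_score[idx] / (dist + 1e-6)

    uniq = np.unique(labels_a)
    votes = np.zeros((len(emb_b), len(uniq)))
    for j, lab in enumerate(uniq):
        votes[:, j] = np.where(anchor_lab[idx] == lab, w, 0.0).sum(axis=1)
    tot = votes.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    conf = votes / tot
    best = conf.argmax(axis=1)
    return TransferResult(
        predicted_label=uniq[best],
        confidence=conf[np.arange(len(emb_b)), best],
        anchors=anchors,
    )


def integrate(norm_a: NormalizedMatrix, norm_b: NormalizedMatrix,
              shared_genes: list[str], anchors: list[tuple[int, int, float]],
              k_weight: int = 10) -> np.ndarray:
    """Anchor-weighted correction of B toward A on the shared gene space.

    Returns the merged scaled matrix (genes x (cells_A + cells_B)); species
    A columns are passed through unchanged (reference convention).
    """
    genes = sorted(shared_genes)
    Xa, Xb = _shared_scaled(norm_a, norm_b, genes)
    anchor_a = np.array([a for a, _, _ in anchors])
    anchor_b = np.array([b for _, b, _ in anchors])
    score = np.array([s for _, _, s in anchors])
    diff = Xb[:, anchor_b] - Xa[:, anchor_a]  # genes x anchors

    kw = min(k_weight, len(anchors))
    nn = NearestNeighbors(n_neighbors=kw).fit(Xb[:, anchor_b].T)
    dist, idx = nn.kneighbors(Xb.T)
    w = score[idx] / (dist + 1e-6)
    w = w / np.maximum(w.sum(axis=1, keepdims=True), 1e-12)
    # per-cell weighted average of its nearest anchors' difference vectors
    corrected = Xb - np.stack(
        [diff[:, idx[c]] @ w[c] for c in range(Xb.shape[1])], axis=1)
    return np.concatenate([Xa, corrected], axis=1)


def integrated_clusters(norm_a: NormalizedMatrix, norm_b: NormalizedMatrix,
                        shared_genes: list[str],
                        anchors: list[tuple[int, int, float]],
                        seed: int = 0) -> tuple[_cluster.ClusterSolution, pd.DataFrame]:
    """Joint clustering of the anchor-corrected merged matrix, plus a
    per-cluster species-proportion report."""
    merged = integrate(norm_a, norm_b, shared_genes, anchors)
    emb = _cluster.pca_elbow(merged, seed=seed)
    sol = _cluster.optimize_clustering(emb.retained, seed=seed)
    species = np.array(["A"] * norm_a.n_cells + ["B"] * norm_b.n_cells)
    tab = pd.crosstab(pd.Series(sol.labels, name="cluster"),
                      pd.Series(species, name="species"))
    prop = tab.div(tab.sum(axis=1), axis=0)
    return sol, prop


def cross_species_markers(markers_a: pd.DataFrame, markers_b: pd.DataFrame,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Combine per-species marker tables (combined_p columns) over shared
    (gene, cluster) rows with the logit method."""
    from .markers import combine_logitp
    from statsmodels.stats.multitest import multipletests

    shared = markers_a.index.intersection(markers_b.index)
    if len(shared) == 0:
        raise ValueError("no shared (gene, cluster) rows")
    pa = markers_a.loc[shared, "combined_p"].to_numpy(dtype=float)
    pb = markers_b.loc[shared, "combined_p"].to_numpy(dtype=float)
    ok = np.isfinite(pa) & np.isfinite(pb)
    combined = np.full(len(shared), np.nan)
    combined[ok] = [combine_logitp([x, y]) for x, y in zip(pa[ok], pb[ok])]
    out = pd.DataFrame(index=shared)
    out["p_A"] = pa
    out["p_B"] = pb
    out["combined_p"] = combined
    out["fdr_q"] = np.nan
    if ok.sum():
        out.loc[ok, "fdr_q"] = multipletests(combined[ok], method="fdr_bh")[1]
    out["significant"] = out["fdr_q"] < alpha
    return out
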