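"""Gene and cell quality control, and doublet scoring/removal.

Filtering rules: a gene is kept only if detected (count > 0) in at least
``min_cells`` cells in *every* sample, and — for the reference species —
is neither a gene model ("Gm" prefix) nor mitochondrial ("mt-"/"MT-").
Cells need at least ``min_genes`` detected genes.  Doublets are scored by
a kNN classifier against simulated doublets (sums of random cell pairs)
in PCA space, and the expected number of doublets — a linear function of
cell number — is removed from the top of the score distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import ExpressionMatrix


@dataclass
class QCReport:
    genes_removed_by_rule: dict[str, int] = field(default_factory=dict)
    cells_removed_low_genes: int = 0
    doublets_expected: int = 0
    doublets_removed: int = 0
    doublet_scores: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "genes_removed_by_rule": dict(self.genes_removed_by_rule),
            "cells_removed_low_genes": int(self.cells_removed_low_genes),
            "doublets_expected": int(self.doublets_expected),
            "doublets_removed": int(self.doublets_removed),
        }


def _is_gm(gene_ids: np.ndarray) -> np.ndarray:
    return np.array([g.startswith("Gm") for g in gene_ids], dtype=bool)


def _is_mito(gene_ids: np.ndarray) -> np.ndarray:
    return np.array([g.lower().startswith("mt-") for g in gene_ids], dtype=bool)


def filter_genes(matrices: list[ExpressionMatrix], min_cells: int = 4,
                 drop_gm: bool | None = None, drop_mito: bool | None = None,
                 ) -> tuple[list[ExpressionMatrix], QCReport]:
    """Keep genes detected in >= min_cells cells in every sample.

    ``drop_gm``/``drop_mito`` default to True for species A and False for
    species B (gene models and mitochondrial genes are only removed in the
    reference species).
    """
    if not matrices:
        raise ValueError("no samples")
    gene_ids = matrices[0].gene_ids
    for m in matrices[1:]:
        if not np.array_equal(m.gene_ids, gene_ids):
            raise ValueError("samples must share one gene universe")

    species = matrices[0].species
    if drop_gm is None:
        drop_gm = species == "A"
    if drop_mito is None:
        drop_mito = species == "A"

    keep = np.ones(len(gene_ids), dtype=bool)
    report = QCReport()
    n_cells_expr = np.vstack([
        np.asarray((m.counts > 0).sum(axis=1)).ravel() for m in matrices
    ])
    low = (n_cells_expr < min_cells).any(axis=0)
    report.genes_removed_by_rule["min_cells"] = int(low.sum())
    keep &= ~low
    if drop_gm:
        gm = _is_gm(gene_ids)
        report.genes_removed_by_rule["gm_prefix"] = int((gm & keep).sum())
        keep &= ~gm
    if drop_mito:
        mt = _is_mito(gene_ids)
        report.genes_removed_by_rule["mito"] = int((mt & keep).sum())
        keep &= ~mt

    if not keep.any():
        worst = max(report.genes_removed_by_rule,
                    key=report.genes_removed_by_rule.get)
        raise ValueError(f"all genes removed; dominating rule: {worst}")
    return [m.subset_genes(keep) for m in matrices], report


def filter_cells(matrix: ExpressionMatrix,
                 min_genes: int = 500) -> ExpressionMatrix:
    """Keep cells with at least ``min_genes`` detected genes."""
    detected = matrix.genes_detected_per_cell()
    keep = detected >= min_genes
    if not keep.any():
        raise ValueError("all cells removed by the detected-genes filter")
    return matrix.subset_cells(keep)


def doublet_scores(matrix: ExpressionMatrix, k_neighbors: int = 20,
                   n_simulated: int | None = None, n_pcs: int = 30,
                   seed: int = 0) -> np.ndarray:
    """Score each cell by the fraction of its kNN that are simulated doublets.

    Simulated doublets are sums of random cell pairs; observed and simulated
    cells are embedded together by PCA of log1p-CPM profiles, and each
    observed cell's score is the simulated fraction among its ``k_neighbors``
    nearest embedded neighbors.  Scores lie in [0, 1].
    """
    n = matrix.n_cells
    if n < 2:
        raise ValueError("need at least 2 cells")
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be < n_cells")
    if n_simulated is None:
        n_simulated = n
    rng = np.random.default_rng(seed)

    counts = matrix.counts.tocsc().astype(np.float64)
    pairs_a = rng.integers(0, n, size=n_simulated)
    pairs_b = rng.integers(0, n, size=n_simulated)
    sim = counts[:, pairs_a] + counts[:, pairs_b]

    combined = sp.hstack([counts, sim], format="csc")
    lib = np.asarray(combined.sum(axis=0)).ravel()
    lib[lib == 0] = 1.0
    X = combined.multiply(1e4 / lib).tocsc()
    X.data = np.log1p(X.data)
    X = X.toarray().T  # cells x genes

    n_comp = min(n_pcs, X.shape[0] - 1, X.shape[1])
    emb = PCA(n_components=n_comp, svd_solver="randomized",
              random_state=int(seed) % (2**31)).fit_transform(X)

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n])
    neigh = idx[:, 1:]  # drop self
    return (neigh >= n).mean(axis=1)


def remove_doublets(matrix: ExpressionMatrix, scores: np.ndarray,
                    beta: float = 8.0e-6) -> tuple[ExpressionMatrix, QCReport]:
    """Remove the expected number of doublets from the top of the score
    distribution.

    The expected doublet *rate* grows linearly with the number of loaded
    cells (rate = beta * n_cells), so n_removed = round(beta * n^2), clipped
    to [0, n].  Ties in score are broken by cell id for determinism.
    """
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    n = matrix.n_cells
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (n,):
        raise ValueError("scores not aligned to cells")
    rate = beta * n
    n_removed = int(np.clip(round(rate * n), 0, n))

    order = np.lexsort((matrix.cell_ids, -scores))  # score desc, id asc
    drop = np.zeros(n, dtype=bool)
    drop[order[:n_removed]] = True

    report = QCReport(doublets_expected=n_removed, doublets_removed=n_removed,
                      doublet_scores=scores)
    if n_removed == n:
        raise ValueError("doublet removal would empty the matrix")
    return matrix.subset_cells(~drop), report
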