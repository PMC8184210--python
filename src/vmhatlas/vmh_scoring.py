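"""TRAP-guided VMH similarity score and marker-based cluster gating.

The score is the first principal component of the scaled expression of
TRAP bead-enriched genes (those above 1 CPM), sign-oriented so that high
scores mean high aggregate expression of the enriched set.  A cluster is
called VMH when three gates all hold: high TRAP loading (cluster mean
score above the global mean), glutamatergic identity (vesicular glutamate
transporter above its grand mean, both GABAergic markers at or below
theirs), and expression of at least one VMH identity gene (Nr5a1/Fezf1)
above its grand mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .containers import NormalizedMatrix

DEFAULT_MARKERS = {
    "pos_glut": "Slc17a6",
    "neg_gaba": ("Gad1", "Slc32a1"),
    "id_genes": ("Nr5a1", "Fezf1"),
}


@dataclass
class VMHScoreResult:
    cell_score: np.ndarray
    cluster_mean_score: dict[int, float]
    gates: dict[int, dict[str, bool]] = field(default_factory=dict)
    vmh_call: dict[int, bool] = field(default_factory=dict)

    @property
    def vmh_clusters(self) -> set[int]:
        return {c for c, v in self.vmh_call.items() if v}


def vmh_score(norm: NormalizedMatrix, enriched_genes: set[str],
              mean_cpm: dict[str, float] | None = None,
              min_cpm: float = 1.0, seed: int = 0) -> np.ndarray:
    """Per-cell VMH similarity score (oriented PC1 of the enriched-gene
    scaled submatrix).

    ``mean_cpm`` (gene -> mean CPM, e.g. from the TRAP table) applies the
    above-one-CPM expression filter; omit it to use all enriched genes
    present in the matrix.
    """
    present = [g for g in norm.gene_ids if g in enriched_genes]
    if mean_cpm is not None:
        present = [g for g in present if mean_cpm.get(g, 0.0) > min_cpm]
    if len(present) < 2:
        raise ValueError("need >= 2 enriched genes passing the CPM filter")
    if norm.scaled is None:
        raise ValueError("matrix must be scaled first (scale_rows)")
    # fixed gene order for order-invariance
    present = sorted(present)
    idx = [norm.gene_index(g) for g in present]
    sub = norm.scaled[idx, :]  # genes x cells

    pca = PCA(n_components=1, svd_solver="full")
    score = pca.fit_transform(sub.T).ravel()
    summary = sub.mean(axis=0)
    if np.corrcoef(score, summary)[0, 1] < 0:
        score = -score
    return score


def gate_clusters(norm: NormalizedMatrix, labels: np.ndarray,
                  score: np.ndarray,
                  markers: dict | None = None) -> VMHScoreResult:
    """Apply the three VMH gates to every cluster.

    All comparisons are strict ">" against the grand mean over all cells
    (equality fails a gate); the GABAergic exclusion requires cluster means
    of both inhibitory markers to be <= their grand means.
    """
    markers = markers or DEFAULT_MARKERS
    labels = np.asarray(labels)
    score = np.asarray(score, dtype=float)

    needed = [markers["pos_glut"], *markers["neg_gaba"], *markers["id_genes"]]
    missing = [g for g in needed if g not in set(norm.gene_ids)]
    if missing:
        raise ValueError(f"missing marker genes: {missing}")

    expr = {g: norm.values[norm.gene_index(g)] for g in needed}
    grand = {g: v.mean() for g, v in expr.items()}
    global_score = score.mean()

    result = VMHScoreResult(cell_score=score, cluster_mean_score={})
    for c in np.unique(labels):
        c = int(c)
        in_c = labels == c
        mean_score = float(score[in_c].mean())
        result.cluster_mean_score[c] = mean_score
        cl_mean = {g: expr[g][in_c].mean() for g in needed}
        high_loading = mean_score > global_score
        glut = (cl_mean[markers["pos_glut"]] > grand[markers["pos_glut"]]
                and all(cl_mean[g] <= grand[g] for g in markers["neg_gaba"]))
        ident = any(cl_mean[g] > grand[g] for g in markers["id_genes"])
        result.gates[c] = {"high_loading": high_loading,
                           "glutamatergic": glut,
                           "nr5a1_or_fezf1": ident}
        result.vmh_call[c] = high_loading and glut and ident
    return result
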