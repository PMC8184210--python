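"""Collapse fine clusters into major classes by cutting a hierarchy.

Clusters are leaves of an average-linkage tree built on 1 - Pearson
correlation of their mean log-normalized expression over the
variable-gene set.  Cutting the tree at k = 2..K classes gives, per cut,
the maximal and the median-of-maxima pairwise profile correlation among
classes, plus the mean silhouette width of cells labeled by class.  The
selected class count is the largest k at which no pair of classes is
highly correlated — the largest parcellation whose classes all remain
transcriptomically distinct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cluster import mean_silhouette
from .containers import NormalizedMatrix


@dataclass
class TreeCutProfile:
    cut_labels: dict[int, dict[int, int]]  # k -> {cluster: class}
    median_max_corr: dict[int, float] = field(default_factory=dict)
    max_corr: dict[int, float] = field(default_factory=dict)
    mean_silhouette_width: dict[int, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        ks = sorted(self.cut_labels)
        return pd.DataFrame({
            "k": ks,
            "median_max_corr": [self.median_max_corr[k] for k in ks],
            "max_corr": [self.max_corr.get(k, np.nan) for k in ks],
            "mean_silhouette_width": [self.mean_silhouette_width.get(k, np.nan)
                                      for k in ks],
        })


def _cluster_profiles(norm: NormalizedMatrix, labels: np.ndarray,
                      gene_set) -> tuple[np.ndarray, np.ndarray]:
    """Mean log-normalized expression profile per cluster over gene_set.

    Profiles are deliberately unscaled: Pearson correlation between mean
    expression profiles is the similarity the tree and its cuts are judged
    on, and shared baseline expression is part of that similarity.
    """
    genes = sorted(set(gene_set) & set(norm.gene_ids))
    if len(genes) < 2:
        raise ValueError("gene set too small")
    idx = [norm.gene_index(g) for g in genes]
    sub = norm.values[idx, :]
    uniq = np.unique(labels)
    profiles = np.vstack([sub[:, labels == l].mean(axis=1) for l in uniq])
    return profiles, uniq  # clusters x genes


def class_tree(norm: NormalizedMatrix, cluster_labels: np.ndarray,
               gene_set) -> np.ndarray:
    """Average-linkage tree over cluster mean profiles (1 - Pearson r)."""
    labels = np.asarray(cluster_labels)
    if len(np.unique(labels)) < 3:
        raise ValueError("need >= 3 clusters")
    profiles, _ = _cluster_profiles(norm, labels, gene_set)
    if np.any(profiles.std(axis=1) == 0):
        raise ValueError("constant cluster profile; correlations undefined")
    corr = np.corrcoef(profiles)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    return linkage(squareform(dist, checks=False), method="average")


def cut_profile(tree: np.ndarray, norm: NormalizedMatrix,
                cluster_labels: np.ndarray, scores: np.ndarray,
                gene_set, silhouette_subsample: int = 5000,
                seed: int = 0) -> TreeCutProfile:
    """Evaluate every cut k = 2..K of the tree.

    For each k: classes from the hierarchical cut; per-class mean
    log-expression profile; max and median-of-maxima pairwise correlation
    among classes; mean silhouette of cells under the class labeling in
    PC space.
    """
    labels = np.asarray(cluster_labels)
    profiles, uniq = _cluster_profiles(norm, labels, gene_set)
    K = len(uniq)
    cell_sub = norm.values[[norm.gene_index(g)
                            for g in sorted(set(gene_set) & set(norm.gene_ids))], :]

    out = TreeCutProfile(cut_labels={})
    for k in range(2, K + 1):
        cl = fcluster(tree, t=k, criterion="maxclust") - 1
        mapping = {int(uniq[i]): int(cl[i]) for i in range(K)}
        out.cut_labels[k] = mapping
        class_labels = np.array([mapping[int(l)] for l in labels])

        present = np.unique(class_labels)
        class_prof = np.vstack([cell_sub[:, class_labels == c].mean(axis=1)
                                for c in present])
        if len(present) < 2:
            out.median_max_corr[k] = 1.0
            out.max_corr[k] = 1.0
            out.mean_silhouette_width[k] = np.nan
            continue
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(class_prof)
        np.fill_diagonal(corr, -np.inf)
        per_class_max = corr.max(axis=1)
        out.median_max_corr[k] = float(np.median(per_class_max))
        out.max_corr[k] = float(per_class_max.max())
        out.mean_silhouette_width[k] = mean_silhouette(
            scores, class_labels, subsample=silhouette_subsample, seed=seed)
    return out


def select_k(profile: TreeCutProfile, tau: float = 0.5) -> int:
    """Largest k at which no pair of classes is highly correlated.

    Selection uses the cut's *maximum* pairwise profile correlation: the
    first cut beyond the true class level reunites the most-correlated
    merge, so the maximum — unlike the median, which only moves once most
    classes are split — jumps above tau exactly where distinctness is
    lost.  k* = max{k : max_corr(k) <= tau}; if no cut qualifies, 2.
    """
    ks = [k for k, v in profile.max_corr.items() if v <= tau]
    if not ks:
        warnings.warn("no cut satisfies the correlation threshold; using k=2")
        return 2
    return max(ks)


def composition_table(fine_labels: np.ndarray,
                      coarse_labels: np.ndarray) -> pd.DataFrame:
    """Row-percentage cross-tab: share of each fine cluster's cells that
    fall in each coarse class (rows sum to 100)."""
    fine_labels = np.asarray(fine_labels)
    coarse_labels = np.asarray(coarse_labels)
    if fine_labels.shape != coarse_labels.shape:
        raise ValueError("label vectors differ in length")
    tab = pd.crosstab(pd.Series(fine_labels, name="cluster"),
                      pd.Series(coarse_labels, name="class"))
    return tab.div(tab.sum(axis=1), axis=0) * 100.0
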