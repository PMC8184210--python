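"""Per-sample marker detection, logit-method p-value combination, and
curated-marker-set cluster annotation.

Markers are tested per sample with a one-sided Wilcoxon rank-sum test
(in-cluster > rest) and the per-sample p-values are combined with the
Mudholkar-George logit method:

    T = -sum(logit(p_i)),  C = sqrt(k pi^2 (5k + 2) / (3 (5k + 4))),
    p_combined = P(t_{5k+4} > T / C).

Clusters are then annotated against curated CNS cell-type gene sets by
hypergeometric overlap of their significant markers: two or more
significant sets -> "doublets", none -> "junk", exactly one -> that type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import NormalizedMatrix


@dataclass
class AnnotationResult:
    assigned: dict[int, str]
    enrichment_p: pd.DataFrame = field(default_factory=pd.DataFrame)


def combine_logitp(p_values) -> float:
    """Mudholkar-George logit-method combined p-value.

    Each p is clipped to [1e-300, 1 - 1e-16].  With a single p the result
    is a strictly monotone transform of it, not the identity.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    p = np.clip(p, 1e-300, 1.0 - 1e-16)
    k = p.size
    T = -np.sum(np.log(p / (1.0 - p)))
    C = np.sqrt(k * np.pi**2 * (5 * k + 2) / (3.0 * (5 * k + 4)))
    return float(stats.t.sf(T / C, df=5 * k + 4))


def per_sample_markers(norm: NormalizedMatrix, labels: np.ndarray,
                       min_frac: float = 0.1) -> dict[str, pd.DataFrame]:
    """One-sided rank-sum marker tests for every (gene, cluster), per sample.

    Returns sample_id -> DataFrame with MultiIndex (gene, cluster) and
    columns p, log2fc, frac_in, frac_out.  Genes expressed in fewer than
    ``min_frac`` of in-cluster cells, and clusters absent from a sample,
    yield missing (NaN) p-values.
    """
    labels = np.asarray(labels)
    samples = (norm.cell_samples if norm.cell_samples is not None
               else np.array(["sample"] * norm.n_cells, dtype=object))
    clusters = np.unique(labels)
    out: dict[str, pd.DataFrame] = {}
    eps = 1e-9

    gene_col = np.tile(norm.gene_ids, len(clusters))
    clus_col = np.repeat(clusters, norm.n_genes)
    for s in np.unique(samples):
        cols = samples == s
        X = norm.values[:, cols]
        lab = labels[cols]
        blocks = []
        for c in clusters:
            in_c = lab == c
            if in_c.sum() == 0 or (~in_c).sum() == 0:
                blocks.append(np.full((norm.n_genes, 4), np.nan))
                continue
            Xi, Xo = X[:, in_c], X[:, ~in_c]
            frac_in = (Xi > 0).mean(axis=1)
            frac_out = (Xo > 0).mean(axis=1)
            lfc = np.log2((Xi.mean(axis=1) + eps) / (Xo.mean(axis=1) + eps))
            res = stats.mannwhitneyu(Xi, Xo, axis=1, alternative="greater",
                                     method="asymptotic")
            p = np.where(frac_in >= min_frac, res.pvalue, np.nan)
            blocks.append(np.column_stack([p, lfc, frac_in, frac_out]))
        df = pd.DataFrame(np.vstack(blocks),
                          columns=["p", "log2fc", "frac_in", "frac_out"])
        df.insert(0, "gene", gene_col)
        df.insert(1, "cluster", clus_col.astype(int))
        out[str(s)] = df.set_index(["gene", "cluster"])
    return out


def combine_markers(per_sample: dict[str, pd.DataFrame],
                    alpha: float = 0.05) -> pd.DataFrame:
    """Combine per-sample marker p-values with the logit method.

    Missing per-sample p-values (cluster absent, or gene below the
    expressed fraction) are dropped and k adjusted.  BH adjustment is
    applied within each cluster across its tested genes.
    """
    sample_ids = sorted(per_sample)
    merged = pd.concat({s: per_sample[s]["p"] for s in sample_ids}, axis=1)
    effects = pd.concat({s: per_sample[s]["log2fc"] for s in sample_ids}, axis=1)
    fin = pd.concat({s: per_sample[s]["frac_in"] for s in sample_ids}, axis=1)
    fout = pd.concat({s: per_sample[s]["frac_out"] for s in sample_ids}, axis=1)

    P = merged.to_numpy(dtype=float)
    k = np.isfinite(P).sum(axis=1)
    combined = np.full(P.shape[0], np.nan)
    # vectorized Mudholkar-George across rows grouped by k
    for kk in np.unique(k[k > 0]):
        sel = k == kk
        ps = np.clip(P[sel], 1e-300, 1 - 1e-16)
        T = -np.nansum(np.log(ps / (1 - ps)), axis=1)
        C = np.sqrt(kk * np.pi**2 * (5 * kk + 2) / (3.0 * (5 * kk + 4)))
        combined[sel] = stats.t.sf(T / C, df=5 * kk + 4)

    out = pd.DataFrame(index=merged.index)
    out["combined_p"] = combined
    out["n_samples"] = k
    out["log2fc"] = effects.mean(axis=1)
    out["frac_expressed_in"] = fin.mean(axis=1)
    out["frac_expressed_out"] = fout.mean(axis=1)

    out["fdr_q"] = np.nan
    for c in out.index.get_level_values("cluster").unique():
        sel = out.index.get_level_values("cluster") == c
        pvals = out.loc[sel, "combined_p"]
        ok = pvals.notna()
        if ok.sum():
            q = multipletests(pvals[ok], method="fdr_bh")[1]
            out.loc[pvals[ok].index, "fdr_q"] = q
    out["significant"] = (out["fdr_q"] < alpha) & (out["log2fc"] > 0)
    return out


def annotate_clusters(markers: pd.DataFrame, curated_sets: dict[str, set],
                      alpha: float = 0.05) -> AnnotationResult:
    """Annotate clusters by hypergeometric overlap with curated gene sets.

    A cluster enriched (p < alpha) for two or more sets is "doublets";
    for none, "junk"; for exactly one, that set's name.
    """
    if not curated_sets or any(len(s) == 0 for s in curated_sets.values()):
        raise ValueError("curated sets must be nonempty")
    universe = set(markers.index.get_level_values("gene"))
    N = len(universe)
    assigned: dict[int, str] = {}
    rows = {}
    for c in markers.index.get_level_values("cluster").unique():
        sub = markers.xs(int(c), level="cluster")
        marker_genes = set(sub.index[sub["significant"].fillna(False)])
        ps = {}
        for name, gset in curated_sets.items():
            gset = set(gset) & universe
            overlap = len(marker_genes & gset)
            # upper-tail hypergeometric: P(X >= overlap)
            ps[name] = float(stats.hypergeom.sf(
                overlap - 1, N, len(gset), len(marker_genes))) if marker_genes else 1.0
        rows[int(c)] = ps
        hits = [n for n, p in ps.items() if p < alpha]
        if len(marker_genes) == 0 or len(hits) == 0:
            assigned[int(c)] = "junk"
        elif len(hits) >= 2:
            assigned[int(c)] = "doublets"
        else:
            assigned[int(c)] = hits[0]
    return AnnotationResult(assigned=assigned,
                            enrichment_p=pd.DataFrame(rows).T.sort_index())
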