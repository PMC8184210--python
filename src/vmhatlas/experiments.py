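"""Recovery and calibration experiments on generated data.

These functions re-run the pipeline's core claims from scratch — cluster
and class recovery, enrichment-test calibration and power, VMH scoring,
cross-species mapping — and return the measured quantities.  They are
used both by the validation suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from . import class_selection, cross_species, normalize, qc, trap, vmh_scoring
from .containers import concat_samples
from .pipeline import cluster_chain
from .synthetic import (SynthConfig, generate_snrnaseq, generate_species_pair,
                        generate_trap, simulate_paired_bulk)


def clustering_recovery(seed: int, silhouette_subsample: int = 2000) -> dict:
    """One default-config recovery run: silhouette-optimized clustering vs
    planted subclusters, then tree-cut class selection vs planted classes."""
    cfg = SynthConfig(seed=seed)
    mats, truth = generate_snrnaseq(cfg)
    chain = cluster_chain(mats, seed=seed)
    sol, emb, norm, vg = (chain["solution"], chain["embedding"],
                          chain["norm"], chain["var_genes"])
    cls = truth.cell_class[chain["mask"]]
    sub = cls * 100 + truth.cell_subcluster[chain["mask"]]
    ok = cls >= 0
    ari_sub = adjusted_rand_score(sub[ok], sol.labels[ok])
    ari_cls = adjusted_rand_score(cls[ok], sol.labels[ok])

    tree = class_selection.class_tree(norm, sol.labels, vg.selected)
    profile = class_selection.cut_profile(
        tree, norm, sol.labels, emb.retained, vg.selected,
        silhouette_subsample=silhouette_subsample, seed=seed)
    k_star = class_selection.select_k(profile)
    return {"k": sol.k, "ari_subcluster": ari_sub, "ari_class": ari_cls,
            "k_star": k_star, "n_classes": cfg.n_classes,
            "n_subclusters": cfg.n_classes * cfg.subclusters_per_class}


def enrichment_null_calibration(n_reps: int = 200, n_genes: int = 2000,
                                n_pairs: int = 5, seed: int = 0) -> float:
    """Fraction of global-null genes with wald_p < 0.05 across reps."""
    hits = total = 0
    for rep in range(n_reps):
        bulk = simulate_paired_bulk(n_genes, n_pairs, 0.0,
                                    seed=seed * 100_003 + rep)
        out = trap.paired_nb_test(bulk)
        p = out["wald_p"].dropna()
        hits += (p < 0.05).sum()
        total += len(p)
    return hits / total


def enrichment_power(n_reps: int = 5, n_genes: int = 1500,
                     n_planted: int = 100, log2fc: float = 2.0,
                     n_pairs: int = 5, seed: int = 0) -> dict:
    """Sensitivity and FDR for planted fold changes, aggregated over reps."""
    tp = fn = fp = called = 0
    for rep in range(n_reps):
        fc = np.zeros(n_genes)
        fc[:n_planted] = log2fc
        bulk = simulate_paired_bulk(n_genes, n_pairs, fc,
                                    seed=seed * 99_991 + rep)
        out = trap.paired_nb_test(bulk)
        tested = out["wald_p"].notna().to_numpy()
        enr = out["enriched"].to_numpy() & tested
        planted = np.zeros(n_genes, dtype=bool)
        planted[:n_planted] = True
        tp += (enr & planted).sum()
        fn += (~enr & planted & tested).sum()
        fp += (enr & ~planted).sum()
        called += enr.sum()
    return {"sensitivity": tp / (tp + fn), "fdr": fp / max(called, 1)}


def vmh_scoring_experiment(seed: int = 7, chain: dict | None = None,
                           data=None) -> dict:
    """AUROC of the TRAP-guided score for target-class membership, and
    exactness of the three-gate VMH call at the cluster level."""
    from collections import Counter

    if data is None:
        cfg = SynthConfig(seed=seed)
        mats, truth = generate_snrnaseq(cfg)
    else:
        cfg, mats, truth = data
    if chain is None:
        chain = cluster_chain(mats, seed=cfg.seed)
    bulk = generate_trap(cfg, truth, n_pairs=5)
    table = trap.paired_nb_test(bulk)
    enriched = set(table.index[table["enriched"].astype(bool)])
    norm, sol = chain["norm"], chain["solution"]
    score = vmh_scoring.vmh_score(norm, enriched,
                                  mean_cpm=table["mean_cpm"].to_dict(),
                                  seed=cfg.seed)
    cls = truth.cell_class[chain["mask"]]
    ok = cls >= 0
    is_target = np.isin(cls[ok], sorted(truth.trap_target_classes))
    auroc = roc_auc_score(is_target, score[ok])

    gates = vmh_scoring.gate_clusters(norm, sol.labels, score)
    expected = set()
    for c in np.unique(sol.labels):
        maj = Counter(cls[sol.labels == c]).most_common(1)[0][0]
        if maj in truth.trap_target_classes:
            expected.add(int(c))
    return {"auroc": float(auroc),
            "gates_exact": gates.vmh_clusters == expected,
            "n_vmh_clusters": len(gates.vmh_clusters)}


def cross_species_experiment(seed: int = 5) -> dict:
    """Correlation-map accuracy, transfer accuracy and integration mixing
    on a default species pair (true class labels as the reference)."""
    cfg = SynthConfig(seed=seed)
    mats_a, mats_b, truth = generate_species_pair(cfg)

    def process(mats):
        mats_f, _ = qc.filter_genes(mats)
        kept, masks = [], []
        for m in mats_f:
            ck = m.genes_detected_per_cell() >= 500
            kept.append(m.subset_cells(ck))
            masks.append(ck)
        return concat_samples(kept), np.concatenate(masks)

    merged_a, mask_a = process(mats_a)
    merged_b, mask_b = process(mats_b)
    omap = cross_species.OrthologMap.from_dict(truth.ortholog_map)
    merged_b = cross_species.apply_ortholog_map(merged_b, omap,
                                                matrix_a=merged_a)
    norm_a = normalize.scale_rows(normalize.log_normalize(
        merged_a, normalize.library_size_factors(merged_a)))
    norm_b = normalize.scale_rows(normalize.log_normalize(
        merged_b, normalize.library_size_factors(merged_b)))
    var_a = normalize.variable_genes(norm_a).selected
    var_b = normalize.variable_genes(norm_b).selected

    cls_a = truth.cell_class[mask_a]
    cls_b = truth.cell_class_b[mask_b]
    la = np.where(cls_a >= 0, cls_a, 0)
    lb = np.where(cls_b >= 0, cls_b, 0)
    corr = cross_species.correlation_map(norm_a, la, norm_b, lb, var_a, var_b)
    m = corr.to_numpy()
    map_acc = float((m.argmax(axis=0) == np.arange(m.shape[1])).mean())

    shared = sorted((var_a & var_b) & set(norm_a.gene_ids)
                    & set(norm_b.gene_ids))
    res = cross_species.anchor_transfer(norm_a, la, norm_b, shared, seed=seed)
    ok = cls_b >= 0
    transfer_acc = float((res.predicted_label[ok] == cls_b[ok]).mean())

    sol, prop = cross_species.integrated_clusters(norm_a, norm_b, shared,
                                                  res.anchors, seed=seed)
    return {"correlation_map_accuracy": map_acc,
            "transfer_accuracy": transfer_acc,
            "min_species_proportion": float(prop.min().min()),
            "integrated_k": sol.k}
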