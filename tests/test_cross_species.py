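"""Ortholog mapping, correlation mapping, anchors, transfer, integration."""

import numpy as np
import pytest
import scipy.sparse as sp

from vmhatlas import cross_species, normalize
from vmhatlas.containers import ExpressionMatrix
from vmhatlas.cross_species import OrthologMap


def _mat(counts, gene_ids, prefix="c"):
    counts = np.asarray(counts)
    return ExpressionMatrix(
        counts=sp.csr_matrix(counts), gene_ids=gene_ids,
        cell_ids=[f"{prefix}{i}" for i in range(counts.shape[1])])


def test_ortholog_map_must_be_one_to_one():
    with pytest.raises(ValueError):
        OrthologMap(pairs=[("a", "x"), ("a", "y")])
    with pytest.raises(ValueError):
        OrthologMap(pairs=[("a", "x"), ("b", "x")])
    with pytest.raises(ValueError):
        OrthologMap(pairs=[])


def test_apply_ortholog_map_identity_keeps_expressed_intersection():
    counts_b = np.array([[1, 2], [0, 0], [3, 4]])
    mb = _mat(counts_b, ["x", "y", "z"])
    omap = OrthologMap(pairs=[("X", "x"), ("Y", "y"), ("Z", "z")])
    out = cross_species.apply_ortholog_map(mb, omap)
    assert list(out.gene_ids) == ["X", "Z"]  # y unexpressed, dropped
    counts_a = np.array([[5], [0]])
    ma = _mat(counts_a, ["X", "Z"])
    out2 = cross_species.apply_ortholog_map(mb, omap, matrix_a=ma)
    assert list(out2.gene_ids) == ["X"]  # Z unexpressed in A


def test_apply_ortholog_map_counts_from_truth(species_pair_chain):
    d = species_pair_chain
    cfg = d["config"]
    # mapped gene count = |map| minus genes unexpressed in either species
    assert len(d["omap"].pairs) == round(cfg.n_genes * (1 - cfg.ortholog_drop_frac))
    assert set(d["norm_b"].gene_ids) <= {a for a, _ in d["omap"].pairs}


def test_correlation_map_self_is_diagonal_dominant(species_pair_chain):
    d = species_pair_chain
    corr = cross_species.correlation_map(
        d["norm_a"], np.where(d["class_a"] >= 0, d["class_a"], 0),
        d["norm_a"], np.where(d["class_a"] >= 0, d["class_a"], 0),
        d["var_a"], d["var_a"])
    m = corr.to_numpy()
    assert np.allclose(np.diag(m), 1.0, atol=1e-9)
    assert (m.argmax(axis=1) == np.arange(m.shape[0])).all()


def test_correlation_map_maps_true_ortholog_classes(species_pair_chain):
    d = species_pair_chain
    la = np.where(d["class_a"] >= 0, d["class_a"], 0)
    lb = np.where(d["class_b"] >= 0, d["class_b"], 0)
    corr = cross_species.correlation_map(d["norm_a"], la, d["norm_b"], lb,
                                         d["var_a"], d["var_b"])
    m = corr.to_numpy()
    assert (m.argmax(axis=0) == np.arange(m.shape[1])).all()


def test_correlation_map_symmetry(species_pair_chain):
    d = species_pair_chain
    la = np.where(d["class_a"] >= 0, d["class_a"], 0)
    lb = np.where(d["class_b"] >= 0, d["class_b"], 0)
    ab = cross_species.correlation_map(d["norm_a"], la, d["norm_b"], lb,
                                       d["var_a"], d["var_b"])
    ba = cross_species.correlation_map(d["norm_b"], lb, d["norm_a"], la,
                                       d["var_b"], d["var_a"])
    assert np.allclose(ab.to_numpy(), ba.to_numpy().T, atol=1e-9)


def test_merged_class_correlates_with_both_sources():
    """A class merged in species B correlates best with its two source
    classes in A (the one-to-two pattern)."""
    from vmhatlas.synthetic import SynthConfig, generate_species_pair
    from vmhatlas import qc
    from vmhatlas.containers import concat_samples

    cfg = SynthConfig(seed=2, merge_classes=(2, 3))
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
    omap = OrthologMap.from_dict(truth.ortholog_map)
    merged_b = cross_species.apply_ortholog_map(merged_b, omap,
                                                matrix_a=merged_a)
    norm_a = normalize.scale_rows(normalize.log_normalize(
        merged_a, normalize.library_size_factors(merged_a)))
    norm_b = normalize.scale_rows(normalize.log_normalize(
        merged_b, normalize.library_size_factors(merged_b)))
    var_a = normalize.variable_genes(norm_a).selected
    var_b = normalize.variable_genes(norm_b).selected
    la = np.where(truth.cell_class[mask_a] >= 0,
                  truth.cell_class[mask_a], 0)
    lb = np.where(truth.cell_class_b[mask_b] >= 0,
                  truth.cell_class_b[mask_b], 0)
    corr = cross_species.correlation_map(norm_a, la, norm_b, lb, var_a, var_b)
    top2 = set(corr[2].sort_values(ascending=False).index[:2])
    assert top2 == {2, 3}


def test_anchor_self_transfer_recovers_labels(species_pair_chain):
    d = species_pair_chain
    la = np.where(d["class_a"] >= 0, d["class_a"], 0)
    shared = sorted(d["var_a"] & set(d["norm_a"].gene_ids))
    res = cross_species.anchor_transfer(d["norm_a"], la, d["norm_a"],
                                        shared, seed=0)
    assert (res.predicted_label == la).mean() >= 0.99
    assert ((res.confidence >= 0) & (res.confidence <= 1)).all()


def test_anchor_transfer_deterministic(species_pair_chain):
    d = species_pair_chain
    la = np.where(d["class_a"] >= 0, d["class_a"], 0)
    shared = sorted((d["var_a"] & d["var_b"]) & set(d["norm_b"].gene_ids))
    r1 = cross_species.anchor_transfer(d["norm_a"], la, d["norm_b"],
                                       shared, seed=4)
    r2 = cross_species.anchor_transfer(d["norm_a"], la, d["norm_b"],
                                       shared, seed=4)
    assert np.array_equal(r1.predicted_label, r2.predicted_label)
    assert np.allclose(r1.confidence, r2.confidence)


def test_anchor_transfer_cross_species_accuracy(species_pair_chain):
    d = species_pair_chain
    la = np.where(d["class_a"] >= 0, d["class_a"], 0)
    shared = sorted((d["var_a"] & d["var_b"]) & set(d["norm_b"].gene_ids)
                    & set(d["norm_a"].gene_ids))
    res = cross_species.anchor_transfer(d["norm_a"], la, d["norm_b"],
                                        shared, seed=0)
    ok = d["class_b"] >= 0
    acc = (res.predicted_label[ok] == d["class_b"][ok]).mean()
    assert acc >= 0.90


def test_integration_reference_is_unchanged(species_pair_chain):
    d = species_pair_chain
    la = np.where(d["class_a"] >= 0, d["class_a"], 0)
    shared = sorted((d["var_a"] & d["var_b"]) & set(d["norm_b"].gene_ids)
                    & set(d["norm_a"].gene_ids))
    res = cross_species.anchor_transfer(d["norm_a"], la, d["norm_b"],
                                        shared, seed=0)
    merged = cross_species.integrate(d["norm_a"], d["norm_b"], shared,
                                     res.anchors)
    idx = [d["norm_a"].gene_index(g) for g in shared]
    assert np.array_equal(merged[:, :d["norm_a"].n_cells],
                          d["norm_a"].scaled[idx, :])


def test_integrated_clusters_recover_classes_without_substructure():
    """With a single subcluster per class, joint clustering of the
    integrated pair lands within +-2 of the planted class count and mixes
    the species."""
    from vmhatlas.synthetic import SynthConfig, generate_species_pair
    from vmhatlas import qc
    from vmhatlas.containers import concat_samples

    cfg = SynthConfig(seed=9, subclusters_per_class=1, n_genes=1200,
                      n_cells_per_sample=500, n_samples=2,
                      sub_marker_genes=0, tree_step_sub=0.05)
    mats_a, mats_b, truth = generate_species_pair(cfg)

    def process(mats):
        mats_f, _ = qc.filter_genes(mats)
        kept = [m.subset_cells(m.genes_detected_per_cell() >= 500)
                for m in mats_f]
        return concat_samples(kept)

    merged_a = process(mats_a)
    merged_b = process(mats_b)
    omap = OrthologMap.from_dict(truth.ortholog_map)
    merged_b = cross_species.apply_ortholog_map(merged_b, omap,
                                                matrix_a=merged_a)
    norm_a = normalize.scale_rows(normalize.log_normalize(
        merged_a, normalize.library_size_factors(merged_a)))
    norm_b = normalize.scale_rows(normalize.log_normalize(
        merged_b, normalize.library_size_factors(merged_b)))
    var_a = normalize.variable_genes(norm_a).selected
    var_b = normalize.variable_genes(norm_b).selected
    shared = sorted((var_a & var_b) & set(norm_b.gene_ids)
                    & set(norm_a.gene_ids))
    la = np.zeros(norm_a.n_cells, dtype=int)  # labels unused for anchors
    res = cross_species.anchor_transfer(norm_a, la, norm_b, shared, seed=0)
    sol, prop = cross_species.integrated_clusters(norm_a, norm_b, shared,
                                                  res.anchors, seed=0)
    assert abs(sol.k - cfg.n_classes) <= 2
    assert prop.min().min() >= 0.2


def test_cross_species_markers_combination():
    import pandas as pd

    idx = pd.MultiIndex.from_tuples(
        [("g0", 0), ("g1", 0), ("g2", 1)], names=["gene", "cluster"])
    ma = pd.DataFrame({"combined_p": [0.5, 0.01, 1e-5]}, index=idx)
    mb = pd.DataFrame({"combined_p": [0.5, 1.0, 1e-5]}, index=idx[:3])
    out = cross_species.cross_species_markers(ma, mb)
    assert out.loc[("g0", 0), "combined_p"] == pytest.approx(0.5, abs=1e-9)
    # significant in one species only is pulled toward 1
    assert out.loc[("g1", 0), "combined_p"] > 0.01
    # concordant strong signals stay strong
    assert out.loc[("g2", 1), "combined_p"] < 1e-4
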