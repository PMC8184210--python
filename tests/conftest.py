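"""Shared fixtures: expensive generated datasets are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from vmhatlas import normalize, qc, trap
from vmhatlas.containers import concat_samples
from vmhatlas.pipeline import cluster_chain
from vmhatlas.synthetic import SynthConfig, generate_snrnaseq, generate_species_pair, generate_trap


@pytest.fixture(scope="session")
def default_data():
    """Default-config generated samples + ground truth (seed 7)."""
    cfg = SynthConfig(seed=7)
    mats, truth = generate_snrnaseq(cfg)
    return cfg, mats, truth


@pytest.fixture(scope="session")
def default_chain(default_data):
    """Full preprocessing + clustering chain on the default dataset."""
    cfg, mats, truth = default_data
    return cluster_chain(mats, seed=cfg.seed)


@pytest.fixture(scope="session")
def default_trap(default_data):
    """Paired TRAP bulk + enrichment table for the default dataset."""
    cfg, mats, truth = default_data
    bulk = generate_trap(cfg, truth, n_pairs=5)
    table = trap.paired_nb_test(bulk)
    return bulk, table


@pytest.fixture(scope="session")
def species_pair_chain():
    """Species A/B processed pair for cross-species tests (seed 5)."""
    from vmhatlas import cross_species

    cfg = SynthConfig(seed=5)
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
    merged_b = cross_species.apply_ortholog_map(merged_b, omap, matrix_a=merged_a)
    norm_a = normalize.scale_rows(normalize.log_normalize(
        merged_a, normalize.library_size_factors(merged_a)))
    norm_b = normalize.scale_rows(normalize.log_normalize(
        merged_b, normalize.library_size_factors(merged_b)))
    vg_a = normalize.variable_genes(norm_a)
    vg_b = normalize.variable_genes(norm_b)
    return {
        "config": cfg, "truth": truth, "omap": omap,
        "norm_a": norm_a, "norm_b": norm_b,
        "mask_a": mask_a, "mask_b": mask_b,
        "var_a": vg_a.selected, "var_b": vg_b.selected,
        "class_a": truth.cell_class[mask_a],
        "class_b": truth.cell_class_b[mask_b],
    }


@pytest.fixture(scope="session")
def tiny_matrix():
    """10 genes x 12 cells hand fixture used by the deterministic-filter
    tests: two samples of 6 cells, decoy names, known detection pattern."""
    import scipy.sparse as sp
    from vmhatlas.containers import ExpressionMatrix

    rng = np.random.default_rng(0)
    genes = ["Actb", "Nr5a1", "Gm12345", "mt-Nd1", "Fezf1",
             "Slc17a6", "Gad1", "Esr1", "Dlk1", "MT-Co1"]

    def sample(sample_id, low_gene_cells):
        counts = np.ones((10, 6), dtype=int) * 2
        # "low_gene_cells" rows: gene expressed in only 3 of the 6 cells
        for g in low_gene_cells:
            counts[g, :] = 0
            counts[g, :3] = 1
        return ExpressionMatrix(
            counts=sp.csr_matrix(counts), gene_ids=genes,
            cell_ids=[f"{sample_id}c{i}" for i in range(6)],
            sample_id=sample_id)

    # gene 7 (Esr1) under-detected in sample s1 only; gene 8 in both
    return [sample("s0", [8]), sample("s1", [7, 8])]
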