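"""Synthetic multi-sample snRNA-seq, species-pair and paired TRAP bulk data.

The generator plants the statistical structure the downstream analysis
assumes: top-level neuron classes that split into highly correlated
subclusters (a two-level Gaussian random walk on gene log-means), droplet
doublets at a cell-number-dependent rate, low-quality nuclei, decoy gene
models ("Gm...") and mitochondrial genes ("mt-..."), a divergent second
species related through a 1:1 ortholog map, and paired bead/sup bulk
samples whose bead fraction is enriched for chosen target classes.  Full
ground truth is returned so every downstream stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .containers import ExpressionMatrix, PairedBulkSet

# canonical marker names used by the VMH gating rules; planted with
# class-restricted expression so gating is exercised end to end
GATE_GENES = ("Slc17a6", "Gad1", "Slc32a1", "Nr5a1", "Fezf1")


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters.  Defaults emulate a small VMH-like study:
    six classes of four subclusters each, three samples of 2,000 nuclei."""

    n_classes: int = 6
    subclusters_per_class: int = 4
    n_genes: int = 2500
    n_cells_per_sample: int = 2000
    n_samples: int = 3
    tree_step_class: float = 1.4  # log-mean random-walk step between classes
    tree_step_sub: float = 0.15  # diffuse step between subclusters within a class
    # discrete subcluster identity: sparse strong marker shifts on top of the
    # diffuse step (fine cell types are marker-defined, not diffusely shifted)
    sub_marker_genes: int = 300
    sub_marker_log_fc: float = 3.0
    baseline_logmean_mu: float = 0.0
    baseline_logmean_sd: float = 1.8
    nb_dispersion: float = 0.3
    libsize_sd: float = 0.3
    batch_sd: float = 0.1
    target_libsize: float = 5000.0
    doublet_beta: float = 8.0e-6  # doublet rate per cell = beta * n_cells
    lowq_frac: float = 0.02
    decoy_gm_frac: float = 0.05
    decoy_mt_frac: float = 0.01
    divergence_sd: float = 0.3
    ortholog_drop_frac: float = 0.1
    marker_swap_frac: float = 0.0
    merge_classes: tuple[int, int] | None = None
    marker_genes_per_class: int = 10
    marker_log_fc: float = 3.0  # natural-log bump for planted markers
    trap_target_classes: tuple[int, ...] = (0, 1)
    # shared identity program of the target classes (a VMH-like signature
    # expressed by every target class, the backbone of TRAP enrichment)
    target_program_genes: int = 200
    target_program_log_fc: float = 2.5
    trap_contamination: float = 0.2
    trap_dispersion: float = 0.05
    trap_libsize: float = 3.0e5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tree_step_sub >= self.tree_step_class:
            raise ValueError("tree_step_sub must be < tree_step_class")
        for name in ("lowq_frac", "decoy_gm_frac", "decoy_mt_frac",
                     "ortholog_drop_frac", "marker_swap_frac"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("n_classes", "subclusters_per_class", "n_genes",
                     "n_cells_per_sample", "n_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.marker_genes_per_class * self.n_classes > self.n_genes:
            raise ValueError("more planted markers than genes")
        if self.merge_classes is not None:
            i, j = self.merge_classes
            if not (0 <= i < self.n_classes and 0 <= j < self.n_classes) or i == j:
                raise ValueError("merge_classes indices out of range")
        if any(not 0 <= c < self.n_classes for c in self.trap_target_classes):
            raise ValueError("trap_target_classes out of range")


@dataclass
class SynthTruth:
    """Ground truth for one generated dataset (cells ordered sample by
    sample, matching the concatenation order of the returned matrices)."""

    cell_class: np.ndarray
    cell_subcluster: np.ndarray
    is_doublet: np.ndarray
    is_lowq: np.ndarray
    marker_gene_map: dict[str, int]
    trap_target_classes: set[int]
    trap_enriched_genes: set[str] = field(default_factory=set)
    ortholog_map: dict[str, str] = field(default_factory=dict)
    # species-B per-cell truth (populated by generate_species_pair)
    cell_class_b: np.ndarray | None = None
    cell_subcluster_b: np.ndarray | None = None
    is_doublet_b: np.ndarray | None = None
    is_lowq_b: np.ndarray | None = None


@dataclass
class _ClassModel:
    """Deterministic gene-level model shared by all generators for a config."""

    gene_ids: np.ndarray
    log_mean: np.ndarray  # (n_classes, n_sub, n_genes), natural log scale
    marker_gene_map: dict[str, int]


def _rng_children(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n)]


def _build_class_model(config: SynthConfig, divergence: float = 0.0,
                       swap_rng: np.random.Generator | None = None) -> _ClassModel:
    """Two-level random walk on gene log-means plus planted markers.

    ``divergence`` adds i.i.d. Normal(0, divergence^2) noise to every
    class/subcluster log-mean entry (used for the second species).
    """
    rng, div_rng = _rng_children(config.seed, 5)[:2]
    G, C, S = config.n_genes, config.n_classes, config.subclusters_per_class

    base = rng.normal(config.baseline_logmean_mu, config.baseline_logmean_sd, G)
    class_off = rng.normal(0.0, config.tree_step_class, (C, G))
    sub_off = rng.normal(0.0, config.tree_step_sub, (C, S, G))
    # sparse subcluster markers: each subcluster gets a private set of
    # strongly up-shifted genes
    if config.sub_marker_genes > 0:
        for c in range(C):
            for s in range(S):
                genes = rng.choice(G, size=min(config.sub_marker_genes, G),
                                   replace=False)
                sub_off[c, s, genes] += config.sub_marker_log_fc

    gene_ids = np.array([f"Gene{g:05d}" for g in range(G)], dtype=object)

    # decoys: renamed, never markers or gate genes
    n_gm = int(round(config.decoy_gm_frac * G))
    n_mt = int(round(config.decoy_mt_frac * G))
    n_special = len(GATE_GENES) + config.marker_genes_per_class * C
    decoy_pool = rng.permutation(G)[: n_gm + n_mt + n_special]
    gm_idx = decoy_pool[:n_gm]
    mt_idx = decoy_pool[n_gm:n_gm + n_mt]
    special_idx = decoy_pool[n_gm + n_mt:]
    for k, g in enumerate(gm_idx):
        gene_ids[g] = f"Gm{10000 + k}"
    for k, g in enumerate(mt_idx):
        gene_ids[g] = f"mt-{k}"

    gate_idx = special_idx[: len(GATE_GENES)]
    marker_idx = special_idx[len(GATE_GENES):]
    for name, g in zip(GATE_GENES, gate_idx):
        gene_ids[g] = name

    targets = set(config.trap_target_classes)
    nontargets = [c for c in range(C) if c not in targets]
    log_mean = base[None, None, :] + class_off[:, None, :] + sub_off
    bump = config.marker_log_fc

    # genes with a designed class pattern: the random walk is zeroed so the
    # planted pattern is the only between-class signal, and the baseline is
    # floored so the gene is reliably detected
    def _designed(g: int, classes, fc: float, base_floor: float) -> None:
        log_mean[:, :, g] = max(base[g], base_floor)
        for c in classes:
            log_mean[c, :, g] += fc

    slc17a6, gad1, slc32a1, nr5a1, fezf1 = gate_idx
    _designed(slc17a6, targets, bump, 1.0)
    _designed(nr5a1, targets, bump, 1.0)
    _designed(fezf1, targets, bump, 1.0)
    _designed(gad1, nontargets, bump, 1.0)
    _designed(slc32a1, nontargets, bump, 1.0)

    # shared identity program across all target classes
    if config.target_program_genes > 0:
        program = rng.choice(
            np.setdiff1d(np.arange(G), decoy_pool),
            size=min(config.target_program_genes, G - len(decoy_pool)),
            replace=False)
        for g in program:
            _designed(int(g), targets, config.target_program_log_fc, 0.0)

    marker_gene_map: dict[str, int] = {}
    per_class = config.marker_genes_per_class
    for c in range(C):
        for g in marker_idx[c * per_class:(c + 1) * per_class]:
            target_class = c
            if swap_rng is not None and config.marker_swap_frac > 0 and \
                    swap_rng.random() < config.marker_swap_frac:
                target_class = int(swap_rng.integers(C))
            _designed(int(g), {target_class}, bump, 1.0)
            marker_gene_map[str(gene_ids[g])] = c

    if divergence > 0:
        log_mean = log_mean + div_rng.normal(0.0, divergence, log_mean.shape)

    return _ClassModel(gene_ids=gene_ids, log_mean=log_mean,
                       marker_gene_map=marker_gene_map)


def class_mean_profiles(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Expected relative expression per class (rows sum to 1); also returns
    per-subcluster profiles.  Closed form, no sampling."""
    model = _build_class_model(config)
    sub_prof = np.exp(model.log_mean)  # (C, S, G)
    sub_prof = sub_prof / sub_prof.sum(axis=2, keepdims=True)
    class_prof = sub_prof.mean(axis=1)
    class_prof = class_prof / class_prof.sum(axis=1, keepdims=True)
    return class_prof, sub_prof


def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _generate_cells(config: SynthConfig, model: _ClassModel,
                    seed_stream: np.random.Generator):
    """Draw all samples' cells for one species; returns matrices + truth arrays."""
    C, S, G = config.n_classes, config.subclusters_per_class, config.n_genes
    n = config.n_cells_per_sample
    prof = np.exp(model.log_mean)  # (C, S, G)
    prof = prof / prof.sum(axis=2, keepdims=True)

    class_probs = np.full(C, 1.0 / C)
    matrices = []
    classes_all, subs_all, doub_all, lowq_all = [], [], [], []

    for s_idx in range(config.n_samples):
        rng = np.random.default_rng(seed_stream.integers(2**31))
        batch = rng.normal(0.0, config.batch_sd, G)
        batch_w = np.exp(batch)

        cls = rng.choice(C, size=n, p=class_probs)
        sub = rng.integers(0, S, size=n)
        lib = config.target_libsize * rng.lognormal(0.0, config.libsize_sd, n)

        mean = prof[cls, sub, :] * batch_w[None, :]
        mean = mean / mean.sum(axis=1, keepdims=True) * lib[:, None]
        counts = _nb_sample(rng, mean, config.nb_dispersion)  # cells x genes

        # doublets: overwrite a rate*n subset with thinned sums of two singlets
        n_doub = int(round(config.doublet_beta * n * n))
        is_doub = np.zeros(n, dtype=bool)
        if n_doub > 0:
            med_lib = np.median(counts.sum(axis=1))
            doub_idx = rng.choice(n, size=n_doub, replace=False)
            for i in doub_idx:
                a, b = rng.choice(n, size=2, replace=False)
                summed = counts[a] + counts[b]
                tot = summed.sum()
                keep = min(1.0, 1.5 * med_lib / max(tot, 1))
                counts[i] = rng.binomial(summed, keep)
            is_doub[doub_idx] = True

        # low-quality nuclei: thinned until < 500 genes detected
        n_lowq = int(round(config.lowq_frac * n))
        is_lowq = np.zeros(n, dtype=bool)
        if n_lowq > 0:
            pool = np.flatnonzero(~is_doub)
            lowq_idx = rng.choice(pool, size=min(n_lowq, pool.size), replace=False)
            for i in lowq_idx:
                while (counts[i] > 0).sum() >= 500:
                    counts[i] = rng.binomial(counts[i], 0.5)
            is_lowq[lowq_idx] = True

        cls_out = cls.copy()
        sub_out = sub.copy()
        cls_out[is_doub] = -1
        sub_out[is_doub] = -1

        sample_id = f"sample{s_idx}"
        matrices.append(ExpressionMatrix(
            counts=sp.csr_matrix(counts.T),
            gene_ids=model.gene_ids.copy(),
            cell_ids=np.array([f"cell{s_idx}_{i:05d}" for i in range(n)], dtype=object),
            sample_id=sample_id,
        ))
        classes_all.append(cls_out)
        subs_all.append(sub_out)
        doub_all.append(is_doub)
        lowq_all.append(is_lowq)

    return (matrices, np.concatenate(classes_all), np.concatenate(subs_all),
            np.concatenate(doub_all), np.concatenate(lowq_all))


def generate_snrnaseq(config: SynthConfig) -> tuple[list[ExpressionMatrix], SynthTruth]:
    """Generate per-sample count matrices with planted class structure.

    Returns one ``ExpressionMatrix`` per sample plus the ground truth; cells
    in the truth arrays follow sample order.
    """
    model = _build_class_model(config)
    stream = _rng_children(config.seed, 5)[2]
    matrices, cls, sub, doub, lowq = _generate_cells(config, model, stream)
    truth = SynthTruth(
        cell_class=cls, cell_subcluster=sub, is_doublet=doub, is_lowq=lowq,
        marker_gene_map=model.marker_gene_map,
        trap_target_classes=set(config.trap_target_classes),
    )
    return matrices, truth


def generate_species_pair(config: SynthConfig):
    """Generate species A and a divergent species B sharing class structure.

    B log-means are A log-means plus Normal(0, divergence_sd^2) noise;
    ``ortholog_drop_frac`` of genes are removed from the 1:1 map and renamed
    un-mappably; ``merge_classes`` optionally collapses two classes in B.

    Returns ``(matrices_A, matrices_B, truth)``.
    """
    matrices_a, truth = generate_snrnaseq(config)

    streams = _rng_children(config.seed, 5)
    b_stream, map_rng = streams[3], streams[4]
    model_b = _build_class_model(config, divergence=config.divergence_sd,
                                 swap_rng=map_rng if config.marker_swap_frac else None)

    if config.merge_classes is not None:
        i, j = sorted(config.merge_classes)
        merged = 0.5 * (model_b.log_mean[i] + model_b.log_mean[j])
        model_b.log_mean[i] = merged
        model_b.log_mean[j] = merged

    # rename genes into the B namespace; drop a fraction from the map
    G = config.n_genes
    n_drop = int(round(config.ortholog_drop_frac * G))
    drop = set(map_rng.choice(G, size=n_drop, replace=False).tolist())
    gene_ids_b = np.empty(G, dtype=object)
    ortholog_map: dict[str, str] = {}
    k = 0
    for g in range(G):
        a_name = str(model_b.gene_ids[g])
        if g in drop:
            gene_ids_b[g] = f"BNOVEL{k:05d}"
            k += 1
        else:
            gene_ids_b[g] = f"MMU_{a_name}"
            ortholog_map[a_name] = str(gene_ids_b[g])
    model_b.gene_ids = gene_ids_b

    matrices_b, cls_b, sub_b, doub_b, lowq_b = _generate_cells(
        config, model_b, b_stream)
    for m in matrices_b:
        m.species = "B"
        m.sample_id = "b" + m.sample_id
        m.cell_samples = np.array([m.sample_id] * m.n_cells, dtype=object)

    if config.merge_classes is not None:
        i, j = sorted(config.merge_classes)
        cls_b = np.where(cls_b == j, i, cls_b)

    truth.ortholog_map = ortholog_map
    truth.cell_class_b = cls_b
    truth.cell_subcluster_b = sub_b
    truth.is_doublet_b = doub_b
    truth.is_lowq_b = lowq_b
    return matrices_a, matrices_b, truth


def trap_mixture_profiles(config: SynthConfig, truth: SynthTruth):
    """Closed-form expected sup and bead relative-expression profiles.

    sup = prevalence-weighted mixture over all classes; bead = the same
    mixture re-weighted toward the target classes with a contamination
    fraction of the sup mixture retained.
    """
    class_prof, _ = class_mean_profiles(config)
    ok = (~truth.is_doublet) & (~truth.is_lowq)
    prev = np.bincount(truth.cell_class[ok], minlength=config.n_classes).astype(float)
    prev = prev / prev.sum()

    targets = sorted(truth.trap_target_classes)
    t_prev = np.zeros_like(prev)
    t_prev[targets] = prev[targets]
    t_prev = t_prev / t_prev.sum()

    sup = prev @ class_prof
    bead = (config.trap_contamination * prev
            + (1 - config.trap_contamination) * t_prev) @ class_prof
    sup = sup / sup.sum()
    bead = bead / bead.sum()
    return sup, bead


def generate_trap(config: SynthConfig, truth: SynthTruth, n_pairs: int = 5,
                  enrich_ratio: float = 1.5) -> PairedBulkSet:
    """Paired bead/sup bulk counts enriched for the truth's target classes.

    Each pair shares a log-normal pair effect; counts are NB-sampled around
    the mixture expectations.  Genes whose expected bead/sup ratio reaches
    ``enrich_ratio`` are recorded in ``truth.trap_enriched_genes`` (with
    target classes at half the prevalence and the default contamination,
    target-exclusive genes sit at ratio ~1.7, so 1.5 marks genuine
    target-restricted expression).
    """
    if n_pairs < 2:
        raise ValueError("paired design needs >= 2 pairs")
    sup, bead = trap_mixture_profiles(config, truth)
    model = _build_class_model(config)

    ratio = bead / np.maximum(sup, 1e-300)
    truth.trap_enriched_genes = {
        str(g) for g, r in zip(model.gene_ids, ratio) if r >= enrich_ratio
    }

    rng = np.random.default_rng(config.seed + 101)
    counts = np.zeros((config.n_genes, 2 * n_pairs), dtype=np.int64)
    sample_ids, pair_ids, fractions = [], [], []
    for p in range(n_pairs):
        pair_eff = rng.lognormal(0.0, 0.2)
        for frac, prof in (("bead", bead), ("sup", sup)):
            lib = config.trap_libsize * pair_eff * rng.lognormal(0.0, 0.1)
            mean = prof * lib
            col = len(sample_ids)
            counts[:, col] = _nb_sample(rng, mean, config.trap_dispersion)
            sample_ids.append(f"pair{p}_{frac}")
            pair_ids.append(f"pair{p}")
            fractions.append(frac)

    return PairedBulkSet(
        counts=counts, gene_ids=model.gene_ids,
        sample_ids=np.array(sample_ids, dtype=object),
        pair_id=np.array(pair_ids, dtype=object),
        fraction=np.array(fractions, dtype=object),
    )


def demo_config(seed: int = 0) -> SynthConfig:
    """A small configuration for quick end-to-end runs: four classes of two
    subclusters, two samples of 400 nuclei, 900 genes."""
    return SynthConfig(
        n_classes=4, subclusters_per_class=2, n_genes=900,
        n_cells_per_sample=400, n_samples=2, target_libsize=10000.0,
        sub_marker_genes=90, marker_genes_per_class=8,
        target_program_genes=80, trap_target_classes=(0, 1),
        seed=seed,
    )


def simulate_paired_bulk(n_genes: int, n_pairs: int, log2fc: np.ndarray | float,
                         dispersion: float = 0.05, mean_counts: float = 500.0,
                         seed: int = 0) -> PairedBulkSet:
    """Direct paired bead/sup NB simulation with per-gene planted log2 fold
    changes (0 everywhere gives a global null).  Used for calibration."""
    rng = np.random.default_rng(seed)
    fc = np.broadcast_to(np.asarray(log2fc, dtype=float), (n_genes,))
    base = rng.lognormal(np.log(mean_counts), 1.0, n_genes)
    counts = np.zeros((n_genes, 2 * n_pairs), dtype=np.int64)
    sample_ids, pair_ids, fractions = [], [], []
    for p in range(n_pairs):
        pair_eff = rng.lognormal(0.0, 0.3)
        for frac in ("bead", "sup"):
            mean = base * pair_eff * rng.lognormal(0.0, 0.05)
            if frac == "bead":
                mean = mean * 2.0 ** fc
            col = len(sample_ids)
            counts[:, col] = _nb_sample(rng, mean, dispersion)
            sample_ids.append(f"pair{p}_{frac}")
            pair_ids.append(f"pair{p}")
            fractions.append(frac)
    return PairedBulkSet(
        counts=counts,
        gene_ids=np.array([f"Gene{g:05d}" for g in range(n_genes)], dtype=object),
        sample_ids=np.array(sample_ids, dtype=object),
        pair_id=np.array(pair_ids, dtype=object),
        fraction=np.array(fractions, dtype=object),
    )
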