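"""End-to-end orchestration of the class-discovery workflow on generated
data: simulate -> QC -> normalize -> cluster -> markers -> TRAP test ->
VMH score -> VMH subcluster -> class selection -> cross-species.

Each stage persists its state under ``<outdir>/state`` and its
human-readable outputs under ``<outdir>/<stage>``; with ``resume=True`` a
stage whose state file survives (and whose upstream stages were all
cached) is loaded instead of recomputed.  A manifest records parameters,
per-stage status and output hashes; reruns with one seed are
byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import class_selection, cluster, cross_species, io, markers, normalize, qc, trap, vmh_scoring
from .containers import concat_samples
from .synthetic import SynthConfig, generate_species_pair, generate_trap

log = logging.getLogger("vmhatlas")

STAGES = ["simulate", "qc", "normalize", "cluster", "markers", "trap",
          "vmh_score", "vmh_subcluster", "classes", "xspecies"]


@dataclass
class PipelineConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    seed: int = 0
    min_cells: int = 4
    min_genes: int = 500
    doublet_beta: float = 8.0e-6
    n_top_variable: int = 2000
    tau: float = 0.5
    trap_pairs: int = 5
    marker_min_frac: float = 0.1
    alpha: float = 0.05

    def to_yaml(self, path: str | Path) -> None:
        import yaml
        d = asdict(self)
        synth = d.pop("synth")
        if synth.get("merge_classes") is not None:
            synth["merge_classes"] = list(synth["merge_classes"])
        synth["trap_target_classes"] = list(synth["trap_target_classes"])
        d["synth"] = synth
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        d = yaml.safe_load(Path(path).read_text())
        synth = d.pop("synth", {})
        if synth.get("merge_classes") is not None:
            synth["merge_classes"] = tuple(synth["merge_classes"])
        if "trap_target_classes" in synth:
            synth["trap_target_classes"] = tuple(synth["trap_target_classes"])
        return cls(synth=SynthConfig(**synth), **d)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class Pipeline:
    def __init__(self, config: PipelineConfig, outdir: str | Path,
                 resume: bool = False):
        self.config = config
        self.outdir = Path(outdir)
        self.resume = resume
        self.state: dict = {}
        self.manifest: dict = {"seed": config.seed, "stages": {}}
        self._upstream_recomputed = False
        (self.outdir / "state").mkdir(parents=True, exist_ok=True)

    # -- stage plumbing ----------------------------------------------------
    def _state_file(self, stage: str) -> Path:
        return self.outdir / "state" / f"{stage}.pkl"

    def _run_stage(self, stage: str, fn) -> None:
        sf = self._state_file(stage)
        t0 = time.time()
        if self.resume and sf.exists() and not self._upstream_recomputed:
            with open(sf, "rb") as fh:
                self.state.update(pickle.load(fh))
            status = "cached"
        else:
            fn()
            with open(sf, "wb") as fh:
                pickle.dump(self.state, fh)
            status = "computed"
            self._upstream_recomputed = True
        self.manifest["stages"][stage] = {
            "status": status,
            "seconds": round(time.time() - t0, 3),
            "hash": _hash_file(sf),
        }
        log.info("stage %-14s %s (%.1fs)", stage, status,
                 time.time() - t0)

    def run_all(self) -> dict:
        for stage in STAGES:
            fn = getattr(self, f"_stage_{stage}")
            try:
                self._run_stage(stage, fn)
            except Exception as e:
                raise RuntimeError(f"stage {stage!r} failed: {e}") from e
        self.manifest["config"] = json.loads(
            json.dumps(asdict(self.config), default=list))
        (self.outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True))
        return self.manifest

    # -- stages ------------------------------------------------------------
    def _stage_simulate(self) -> None:
        cfg = self.config.synth
        mats_a, mats_b, truth = generate_species_pair(cfg)
        self.state.update(mats_a=mats_a, mats_b=mats_b, truth=truth)
        d = self.outdir / "simulate"
        for m in mats_a + mats_b:
            io.write_10x(m, d / m.sample_id)
        pd.DataFrame({
            "cell_class": truth.cell_class,
            "cell_subcluster": truth.cell_subcluster,
            "is_doublet": truth.is_doublet,
            "is_lowq": truth.is_lowq,
        }).to_csv(d / "truth_cells.tsv", sep="\t", index=False)
        pd.Series(truth.marker_gene_map).rename("class").to_csv(
            d / "truth_markers.tsv", sep="\t")

    def _stage_qc(self) -> None:
        c = self.config
        mats, gene_report = qc.filter_genes(self.state["mats_a"],
                                            min_cells=c.min_cells)
        kept = []
        qc_reports = {"genes": gene_report.to_dict()}
        for m in mats:
            m = qc.filter_cells(m, min_genes=c.min_genes)
            scores = qc.doublet_scores(m, seed=c.seed)
            m, rep = qc.remove_doublets(m, scores, beta=c.doublet_beta)
            kept.append(m)
            qc_reports[m.sample_id] = rep.to_dict()
        self.state["mats_qc"] = kept
        d = self.outdir / "qc"
        d.mkdir(exist_ok=True)
        (d / "qc_report.json").write_text(json.dumps(qc_reports, indent=2))

    def _stage_normalize(self) -> None:
        merged = concat_samples(self.state["mats_qc"])
        factors = normalize.compute_size_factors(merged, seed=self.config.seed)
        norm = normalize.log_normalize(merged, factors)
        norm = normalize.scale_rows(norm)
        vg = normalize.variable_genes(norm, n_top=self.config.n_top_variable)
        self.state.update(merged=merged, norm=norm, var_genes=vg)
        d = self.outdir / "normalize"
        d.mkdir(exist_ok=True)
        pd.Series(sorted(vg.selected)).to_csv(d / "variable_genes.tsv",
                                              sep="\t", index=False, header=False)

    def _stage_cluster(self) -> None:
        norm, vg = self.state["norm"], self.state["var_genes"]
        genes = sorted(vg.selected)
        idx = [norm.gene_index(g) for g in genes]
        emb = cluster.pca_elbow(norm.scaled[idx, :], seed=self.config.seed)
        sol = cluster.optimize_clustering(emb.retained, seed=self.config.seed)
        labels, Z = (cluster.order_clusters(emb.retained, sol.labels)
                     if sol.k >= 2 else (sol.labels, None))
        sol.labels = labels
        self.state.update(embedding=emb, solution=sol, linkage=Z)
        d = self.outdir / "cluster"
        d.mkdir(exist_ok=True)
        pd.DataFrame({"cell": norm.cell_ids, "cluster": labels}).to_csv(
            d / "labels.tsv", sep="\t", index=False)
        (d / "parameters.json").write_text(json.dumps({
            "n_neighbors": sol.n_neighbors, "resolution": sol.resolution,
            "mean_silhouette": sol.mean_silhouette, "k": sol.k,
            "n_pcs": emb.n_retained}))

    def _stage_markers(self) -> None:
        norm = self.state["norm"]
        sol = self.state["solution"]
        per = markers.per_sample_markers(norm, sol.labels,
                                         min_frac=self.config.marker_min_frac)
        table = markers.combine_markers(per, alpha=self.config.alpha)
        truth = self.state["truth"]
        curated = {}
        for g, c in truth.marker_gene_map.items():
            curated.setdefault(f"class{c}", set()).add(g)
        ann = markers.annotate_clusters(table, curated, alpha=self.config.alpha)
        self.state.update(marker_table=table, annotation=ann)
        d = self.outdir / "markers"
        d.mkdir(exist_ok=True)
        table.reset_index().to_csv(d / "marker_table.tsv", sep="\t", index=False)
        pd.Series(ann.assigned).rename("type").to_csv(d / "annotation.tsv", sep="\t")

    def _stage_trap(self) -> None:
        truth = self.state["truth"]
        bulk = generate_trap(self.config.synth, truth,
                             n_pairs=self.config.trap_pairs)
        table = trap.paired_nb_test(bulk, alpha=self.config.alpha)
        self.state.update(trap_bulk=bulk, trap_table=table)
        d = self.outdir / "trap"
        d.mkdir(exist_ok=True)
        io.write_bulk(bulk, d / "counts.tsv", d / "meta.tsv")
        table.reset_index().to_csv(d / "enrichment.tsv", sep="\t", index=False)

    def _stage_vmh_score(self) -> None:
        norm = self.state["norm"]
        sol = self.state["solution"]
        table = self.state["trap_table"]
        enriched = set(table.index[table["enriched"].astype(bool)])
        cpm_map = table["mean_cpm"].to_dict()
        score = vmh_scoring.vmh_score(norm, enriched, mean_cpm=cpm_map,
                                      seed=self.config.seed)
        gates = vmh_scoring.gate_clusters(norm, sol.labels, score)
        self.state.update(vmh_score=score, vmh_gates=gates)
        # pseudo-TRAP on VMH vs non-VMH cells, per sample
        vmh_cells = np.isin(sol.labels, sorted(gates.vmh_clusters))
        groups = {}
        for m in self.state["mats_qc"]:
            sel = norm.cell_samples == m.sample_id
            groups[m.sample_id] = vmh_cells[sel]
        pseudo = trap.pseudo_trap(self.state["mats_qc"], groups)
        pseudo_table = trap.paired_nb_test(pseudo, alpha=self.config.alpha)
        conc = trap.concordance(self.state["trap_table"], pseudo_table)
        self.state.update(pseudo_table=pseudo_table, concordance=conc)
        d = self.outdir / "vmh_score"
        d.mkdir(exist_ok=True)
        pd.DataFrame({"cell": norm.cell_ids, "score": score,
                      "cluster": sol.labels}).to_csv(
            d / "scores.tsv", sep="\t", index=False)
        (d / "vmh_calls.json").write_text(json.dumps(
            {str(c): bool(v) for c, v in gates.vmh_call.items()}))
        (d / "concordance.json").write_text(json.dumps(conc.sizes()))

    def _stage_vmh_subcluster(self) -> None:
        norm = self.state["norm"]
        sol = self.state["solution"]
        gates = self.state["vmh_gates"]
        vmh_cells = np.isin(sol.labels, sorted(gates.vmh_clusters))
        if vmh_cells.sum() < 50:
            raise RuntimeError("too few VMH cells to subcluster")
        vg = self.state["var_genes"]
        idx = [norm.gene_index(g) for g in sorted(vg.selected)]
        emb = cluster.pca_elbow(norm.scaled[np.ix_(idx, np.flatnonzero(vmh_cells))],
                                seed=self.config.seed)
        sub_sol = cluster.optimize_clustering(emb.retained, seed=self.config.seed)
        self.state.update(vmh_cells=vmh_cells, vmh_embedding=emb,
                          vmh_solution=sub_sol)
        d = self.outdir / "vmh_subcluster"
        d.mkdir(exist_ok=True)
        pd.DataFrame({"cell": norm.cell_ids[vmh_cells],
                      "cluster": sub_sol.labels}).to_csv(
            d / "labels.tsv", sep="\t", index=False)

    def _stage_classes(self) -> None:
        norm = self.state["norm"]
        vmh_cells = self.state["vmh_cells"]
        sub_sol = self.state["vmh_solution"]
        vg = self.state["var_genes"]
        # a view of the normalized matrix restricted to VMH cells
        from .containers import NormalizedMatrix
        sub_norm = NormalizedMatrix(
            values=norm.values[:, vmh_cells],
            size_factors=norm.size_factors[vmh_cells],
            gene_ids=norm.gene_ids, cell_ids=norm.cell_ids[vmh_cells],
            cell_samples=norm.cell_samples[vmh_cells],
            scaled=norm.scaled[:, vmh_cells])
        if sub_sol.k < 3:
            raise RuntimeError("need >= 3 VMH subclusters for the class tree")
        tree = class_selection.class_tree(sub_norm, sub_sol.labels, vg.selected)
        emb = self.state["vmh_embedding"]
        profile = class_selection.cut_profile(tree, sub_norm, sub_sol.labels,
                                              emb.retained, vg.selected,
                                              seed=self.config.seed)
        k_star = class_selection.select_k(profile, tau=self.config.tau)
        mapping = profile.cut_labels[k_star]
        class_labels = np.array([mapping[int(l)] for l in sub_sol.labels])
        comp = class_selection.composition_table(sub_sol.labels, class_labels)
        self.state.update(class_tree=tree, cut_profile=profile,
                          k_star=k_star, class_labels=class_labels)
        d = self.outdir / "classes"
        d.mkdir(exist_ok=True)
        profile.to_frame().to_csv(d / "tree_cut_profile.tsv", sep="\t", index=False)
        comp.to_csv(d / "composition.tsv", sep="\t")
        (d / "selected_k.json").write_text(json.dumps({"k": int(k_star)}))
        (d / "tree.nwk").write_text(io.linkage_to_newick(
            tree, [f"cluster{i}" for i in range(sub_sol.k)]))

    def _stage_xspecies(self) -> None:
        c = self.config
        truth = self.state["truth"]
        # species-B QC (no Gm/mito rule), normalization, clustering
        mats_b, _ = qc.filter_genes(self.state["mats_b"], min_cells=c.min_cells)
        mats_b = [qc.filter_cells(m, min_genes=c.min_genes) for m in mats_b]
        merged_b = concat_samples(mats_b)
        omap = cross_species.OrthologMap.from_dict(truth.ortholog_map)
        merged_b = cross_species.apply_ortholog_map(
            merged_b, omap, matrix_a=self.state["merged"])
        factors_b = normalize.compute_size_factors(merged_b, seed=c.seed)
        norm_b = normalize.scale_rows(normalize.log_normalize(merged_b, factors_b))
        vg_b = normalize.variable_genes(norm_b, n_top=c.n_top_variable)

        norm_a = self.state["norm"]
        vg_a = self.state["var_genes"]
        labels_a = self.state["solution"].labels
        shared = sorted((vg_a.selected & vg_b.selected)
                        & set(norm_a.gene_ids) & set(norm_b.gene_ids))

        idx_b = [norm_b.gene_index(g) for g in sorted(vg_b.selected)]
        emb_b = cluster.pca_elbow(norm_b.scaled[idx_b, :], seed=c.seed)
        sol_b = cluster.optimize_clustering(emb_b.retained, seed=c.seed)

        corr = cross_species.correlation_map(norm_a, labels_a, norm_b,
                                             sol_b.labels, vg_a.selected,
                                             vg_b.selected)
        transfer = cross_species.anchor_transfer(norm_a, labels_a, norm_b,
                                                 shared, seed=c.seed)
        int_sol, prop = cross_species.integrated_clusters(
            norm_a, norm_b, shared, transfer.anchors, seed=c.seed)
        self.state.update(norm_b=norm_b, solution_b=sol_b, xcorr=corr,
                          transfer=transfer, integrated=int_sol,
                          species_prop=prop)
        d = self.outdir / "xspecies"
        d.mkdir(exist_ok=True)
        corr.to_csv(d / "correlation_map.tsv", sep="\t")
        pd.DataFrame({"cell": norm_b.cell_ids,
                      "label": transfer.predicted_label,
                      "confidence": transfer.confidence}).to_csv(
            d / "transfer.tsv", sep="\t", index=False)
        prop.to_csv(d / "species_proportions.tsv", sep="\t")


def cluster_chain(mats, seed: int = 0, min_genes: int = 500,
                  size_factors: str = "library",
                  doublet_beta: float = 8.0e-6) -> dict:
    """Standard preprocessing + clustering chain on a list of samples.

    Returns a dict with the kept-cell mask (relative to the gene-filtered
    input), the normalized matrix, variable genes, embedding and cluster
    solution.  ``size_factors`` is "library" or "deconvolution".
    """
    mats_f, gene_report = qc.filter_genes(mats)
    kept, masks = [], []
    for m in mats_f:
        ck = m.genes_detected_per_cell() >= min_genes
        m2 = m.subset_cells(ck)
        scores = qc.doublet_scores(m2, seed=seed)
        m3, _ = qc.remove_doublets(m2, scores, beta=doublet_beta)
        ids = set(m3.cell_ids)
        mask = ck.copy()
        mask[ck] = np.array([c in ids for c in m2.cell_ids])
        masks.append(mask)
        kept.append(m3)
    merged = concat_samples(kept)
    if size_factors == "deconvolution":
        factors = normalize.compute_size_factors(merged, seed=seed)
    else:
        factors = normalize.library_size_factors(merged)
    norm = normalize.scale_rows(normalize.log_normalize(merged, factors))
    vg = normalize.variable_genes(norm)
    idx = [norm.gene_index(g) for g in sorted(vg.selected)]
    emb = cluster.pca_elbow(norm.scaled[idx, :], seed=seed)
    sol = cluster.optimize_clustering(emb.retained, seed=seed)
    return {"mask": np.concatenate(masks), "merged": merged, "norm": norm,
            "var_genes": vg, "embedding": emb, "solution": sol,
            "gene_report": gene_report}


def demo_pipeline_config(seed: int = 0) -> PipelineConfig:
    """Pipeline configuration for the small demo fixture.  The detected-
    genes threshold is scaled to the fixture's 900-gene universe (the
    default of 500 assumes a full-size transcriptome)."""
    from .synthetic import demo_config
    return PipelineConfig(synth=demo_config(seed), seed=seed, min_genes=350)


def run_all(config: PipelineConfig, outdir: str | Path,
            resume: bool = False) -> dict:
    """Run every stage; returns the manifest."""
    return Pipeline(config, outdir, resume=resume).run_all()
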