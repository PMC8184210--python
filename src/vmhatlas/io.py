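"""Standard-format I/O: 10x-style triplets, bulk TSVs, configs, trees.

MatrixMarket files are 1-based per the standard; every internal index is
0-based.  That boundary lives exactly in this module.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .containers import ExpressionMatrix, PairedBulkSet
from .synthetic import SynthConfig


def write_10x(matrix: ExpressionMatrix, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", sp.coo_matrix(matrix.counts),
                     field="integer")
    pd.Series(matrix.gene_ids).to_csv(outdir / "features.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(matrix.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    meta = {"sample_id": matrix.sample_id, "species": matrix.species}
    (outdir / "sample.json").write_text(json.dumps(meta))
    return outdir


def read_10x(indir: str | Path) -> ExpressionMatrix:
    indir = Path(indir)
    counts = sp.csr_matrix(scipy.io.mmread(indir / "matrix.mtx"))
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    if counts.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix.mtx is {counts.shape} but features/barcodes give "
            f"({len(genes)}, {len(cells)})")
    meta = {"sample_id": indir.name, "species": "A"}
    meta_file = indir / "sample.json"
    if meta_file.exists():
        meta.update(json.loads(meta_file.read_text()))
    return ExpressionMatrix(counts=counts, gene_ids=genes.to_numpy(dtype=object),
                            cell_ids=cells.to_numpy(dtype=object),
                            sample_id=meta["sample_id"], species=meta["species"])


def write_bulk(bulk: PairedBulkSet, counts_path: str | Path,
               meta_path: str | Path) -> None:
    df = pd.DataFrame(bulk.counts, index=bulk.gene_ids, columns=bulk.sample_ids)
    df.index.name = "gene"
    df.to_csv(counts_path, sep="\t")
    meta = pd.DataFrame({"sample": bulk.sample_ids, "pair": bulk.pair_id,
                         "fraction": bulk.fraction})
    meta.to_csv(meta_path, sep="\t", index=False)


def read_bulk(counts_path: str | Path, meta_path: str | Path) -> PairedBulkSet:
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t").set_index("sample").loc[df.columns]
    return PairedBulkSet(
        counts=df.to_numpy(dtype=np.int64),
        gene_ids=df.index.to_numpy(dtype=object),
        sample_ids=df.columns.to_numpy(dtype=object),
        pair_id=meta["pair"].to_numpy(dtype=object),
        fraction=meta["fraction"].to_numpy(dtype=object),
    )


def write_config(config: SynthConfig, path: str | Path) -> None:
    d = asdict(config)
    if d.get("merge_classes") is not None:
        d["merge_classes"] = list(d["merge_classes"])
    d["trap_target_classes"] = list(d["trap_target_classes"])
    Path(path).write_text(yaml.safe_dump(d))


def read_config(path: str | Path) -> SynthConfig:
    d = yaml.safe_load(Path(path).read_text())
    if d.get("merge_classes") is not None:
        d["merge_classes"] = tuple(d["merge_classes"])
    d["trap_target_classes"] = tuple(d["trap_target_classes"])
    return SynthConfig(**d)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    n = len(labels)

    def build(node: int) -> str:
        if node < n:
            return str(labels[node])
        left, right, dist = Z[node - n, 0], Z[node - n, 1], Z[node - n, 2]
        return f"({build(int(left))}:{dist / 2:.6g},{build(int(right))}:{dist / 2:.6g})"

    return build(2 * n - 2) + ";"
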