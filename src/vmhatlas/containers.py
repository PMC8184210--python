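"""Core in-memory containers shared across pipeline stages.

Counts are kept genes x cells (the orientation of 10x-style triplet files);
all downstream modules follow that convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp


def _as_str_array(ids) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    return np.array([str(x) for x in arr.ravel()], dtype=object)


@dataclass
class ExpressionMatrix:
    """Sparse gene-by-cell count matrix for one sample (or a merged set).

    Attributes
    ----------
    counts : scipy.sparse.csr_matrix
        Nonnegative integer counts, shape (n_genes, n_cells).
    gene_ids, cell_ids : arrays of unique strings.
    sample_id : str
        Sample of origin; ``"merged"`` for concatenated sets, in which case
        ``cell_samples`` carries the per-cell sample label.
    species : {"A", "B"}
        Mouse-like reference ("A") or divergent second species ("B").
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    sample_id: str = "sample"
    species: str = "A"
    cell_samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.cell_ids = _as_str_array(self.cell_ids)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")
        if self.cell_samples is None:
            self.cell_samples = np.array(
                [self.sample_id] * len(self.cell_ids), dtype=object
            )
        else:
            self.cell_samples = _as_str_array(self.cell_samples)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, index) -> "ExpressionMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return ExpressionMatrix(
            counts=self.counts[index, :],
            gene_ids=self.gene_ids[index],
            cell_ids=self.cell_ids,
            sample_id=self.sample_id,
            species=self.species,
            cell_samples=self.cell_samples,
        )

    def subset_cells(self, index) -> "ExpressionMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return ExpressionMatrix(
            counts=self.counts[:, index],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[index],
            sample_id=self.sample_id,
            species=self.species,
            cell_samples=self.cell_samples[index],
        )

    def genes_detected_per_cell(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel().astype(float)


def concat_samples(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-concatenate samples sharing an identical gene universe."""
    if not matrices:
        raise ValueError("no matrices to concatenate")
    ref = matrices[0]
    for m in matrices[1:]:
        if not np.array_equal(m.gene_ids, ref.gene_ids):
            raise ValueError("gene universes differ between samples")
    cell_ids = np.concatenate(
        [np.char.add(m.sample_id + ":", m.cell_ids.astype(str)) for m in matrices]
    )
    return ExpressionMatrix(
        counts=sp.hstack([m.counts for m in matrices], format="csr"),
        gene_ids=ref.gene_ids,
        cell_ids=cell_ids,
        sample_id="merged",
        species=ref.species,
        cell_samples=np.concatenate([m.cell_samples for m in matrices]),
    )


@dataclass
class NormalizedMatrix:
    """Log-normalized (and optionally scaled) expression values.

    ``values`` holds log(1 + count / size_factor); ``scaled`` holds per-gene
    z-scores computed per dataset, clipped to bound outlier leverage.
    """

    values: np.ndarray  # genes x cells
    size_factors: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_samples: np.ndarray | None = None
    scaled: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.cell_ids = _as_str_array(self.cell_ids)
        if self.cell_samples is not None:
            self.cell_samples = _as_str_array(self.cell_samples)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        hits = np.flatnonzero(self.gene_ids == gene)
        if hits.size == 0:
            raise KeyError(f"gene {gene!r} not present")
        return int(hits[0])


@dataclass
class PairedBulkSet:
    """Bulk counts for paired bead (IP) / sup (unbound) TRAP fractions."""

    counts: np.ndarray  # genes x samples, nonnegative integers
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    pair_id: np.ndarray
    fraction: np.ndarray  # "bead" or "sup" per sample

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.sample_ids = _as_str_array(self.sample_ids)
        self.pair_id = _as_str_array(self.pair_id)
        self.fraction = _as_str_array(self.fraction)
        if np.any(self.counts < 0):
            raise ValueError("negative bulk counts")
        bad = set(self.fraction) - {"bead", "sup"}
        if bad:
            raise ValueError(f"unknown fractions: {bad}")
        for p in set(self.pair_id):
            fr = self.fraction[self.pair_id == p]
            if sorted(fr) != ["bead", "sup"]:
                raise ValueError(f"pair {p!r} lacks exactly one bead and one sup")

    @property
    def n_pairs(self) -> int:
        return len(set(self.pair_id))
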