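"""Size-factor normalization, CPM, scaling and variable-gene selection.

Size factors come from a pooling-deconvolution scheme: cells are placed on
a ring ordered by library size, sliding pools of several sizes are summed,
each pooled profile is compared with the average cell to give a pool
factor, and per-cell factors are recovered by least squares from the pool
membership system.  Variable genes must pass two independent criteria —
binned standardized dispersion, and variance of Pearson residuals under a
negative-binomial model with a trend-smoothed dispersion — and the
selected set is the intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import lsqr
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import ExpressionMatrix, NormalizedMatrix

DEFAULT_POOL_SIZES = (21, 41, 61, 81, 101)


@dataclass
class VariableGeneSet:
    by_dispersion: set[str]
    by_residual_variance: set[str]

    @property
    def selected(self) -> set[str]:
        return self.by_dispersion & self.by_residual_variance


def size_factors_deconvolution(matrix: ExpressionMatrix,
                               pool_sizes=DEFAULT_POOL_SIZES,
                               seed: int = 0) -> np.ndarray:
    """Pooling-deconvolution size factors, rescaled to mean 1.

    Pool sizes larger than the cell count are clipped; factors that come
    out nonpositive raise (advice: fall back to library-size factors).
    """
    n = matrix.n_cells
    sizes = sorted({min(int(s), max(2, n - 1)) for s in pool_sizes})
    counts = matrix.counts.toarray().astype(float)  # genes x cells
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("zero-count cell; filter cells first")

    order = np.argsort(lib, kind="stable")  # ring ordered by library size
    C = counts[:, order]
    ref = counts.mean(axis=1)
    expressed = ref > 0

    max_s = max(sizes)
    ext = np.concatenate([C, C[:, :max_s]], axis=1)
    S = np.concatenate([np.zeros((C.shape[0], 1)), np.cumsum(ext, axis=1)], axis=1)

    row_blocks, col_blocks, val_blocks, b_blocks = [], [], [], []
    row0 = 0
    starts = np.arange(n)
    for s in sizes:
        pooled = S[:, s:s + n] - S[:, :n]  # genes x n pools (ring starts)
        ratios = pooled[expressed] / ref[expressed, None]
        pool_factor = np.median(ratios, axis=0)
        cols = (starts[:, None] + np.arange(s)[None, :]) % n
        rows = np.repeat(row0 + starts, s)
        row_blocks.append(rows)
        col_blocks.append(cols.ravel())
        val_blocks.append(np.ones(n * s))
        b_blocks.append(pool_factor)
        row0 += n
    # anchor the overall scale: library-size equations with small weight
    w = 0.01
    row_blocks.append(row0 + starts)
    col_blocks.append(starts)
    val_blocks.append(np.full(n, w))
    b_blocks.append(w * lib[order] / lib.mean())
    row0 += n

    A = sp.csr_matrix(
        (np.concatenate(val_blocks),
         (np.concatenate(row_blocks), np.concatenate(col_blocks))),
        shape=(row0, n))
    sol = lsqr(A, np.concatenate(b_blocks), atol=1e-10, btol=1e-10)[0]
    factors = np.empty(n)
    factors[order] = sol
    if np.any(factors <= 0):
        raise ValueError(
            "nonpositive deconvolution factors; consider library-size factors")
    return factors / factors.mean()


def compute_size_factors(matrix: ExpressionMatrix,
                         pool_sizes=DEFAULT_POOL_SIZES,
                         seed: int = 0) -> np.ndarray:
    """Deconvolution factors with automatic library-size fallback.

    A handful of pathological cells can push the least-squares solution
    nonpositive; in that case the advised fallback is applied.
    """
    try:
        return size_factors_deconvolution(matrix, pool_sizes=pool_sizes,
                                          seed=seed)
    except ValueError as e:
        warnings.warn(f"{e}; falling back to library-size factors")
        return library_size_factors(matrix)


def library_size_factors(matrix: ExpressionMatrix) -> np.ndarray:
    lib = matrix.library_sizes()
    if np.any(lib == 0):
        raise ValueError("zero-count cell")
    return lib / lib.mean()


def cpm(matrix: ExpressionMatrix) -> np.ndarray:
    """Counts-per-million: every column scaled to sum 1e6."""
    lib = matrix.library_sizes()
    if np.any(lib == 0):
        raise ValueError("zero-count cell")
    return matrix.counts.toarray() * (1e6 / lib)[None, :]


def log_normalize(matrix: ExpressionMatrix,
                  size_factors: np.ndarray) -> NormalizedMatrix:
    """value = log(1 + count / size_factor)."""
    size_factors = np.asarray(size_factors, dtype=float)
    if np.any(size_factors <= 0):
        raise ValueError("size factors must be positive")
    values = np.log1p(matrix.counts.toarray() / size_factors[None, :])
    return NormalizedMatrix(
        values=values, size_factors=size_factors,
        gene_ids=matrix.gene_ids, cell_ids=matrix.cell_ids,
        cell_samples=matrix.cell_samples,
    )


def scale_rows(norm: NormalizedMatrix, groups: np.ndarray | None = None,
               clip: float = 10.0) -> NormalizedMatrix:
    """Center and scale each gene to z-scores, per dataset independently.

    ``groups`` assigns cells to datasets (default: one dataset).  Constant
    genes scale to 0.  Values are clipped at +/- ``clip``.
    """
    X = norm.values
    scaled = np.empty_like(X)
    if groups is None:
        groups = np.zeros(X.shape[1], dtype=int)
    groups = np.asarray(groups)
    for g in np.unique(groups):
        cols = groups == g
        sub = X[:, cols]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        scaled[:, cols] = (sub - mu) / sd
    norm.scaled = np.clip(scaled, -clip, clip)
    return norm


def _counts_from_norm(norm: NormalizedMatrix) -> np.ndarray:
    return np.expm1(norm.values) * norm.size_factors[None, :]


def variable_genes(norm: NormalizedMatrix, n_top: int = 2000,
                   n_bins: int = 20) -> VariableGeneSet:
    """Dual-criterion variable genes: binned standardized dispersion AND
    high Pearson-residual variance under a trend-dispersion NB model."""
    if norm.n_cells < 2:
        raise ValueError("need >= 2 cells")
    if n_top > norm.n_genes:
        warnings.warn("n_top exceeds gene count; clipping")
        n_top = norm.n_genes

    X = norm.values
    mean_log = X.mean(axis=1)
    var_log = X.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean_log > 0, var_log / mean_log, 0.0)
    nonconst = var_log > 0

    # criterion 1: dispersion z-scored within mean-expression quantile bins
    z = np.full(norm.n_genes, -np.inf)
    qs = np.quantile(mean_log[nonconst], np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(qs, mean_log, side="right") - 1, 0, n_bins - 1)
    for b in range(n_bins):
        sel = (bins == b) & nonconst
        if sel.sum() == 0:
            continue
        d = disp[sel]
        sd = d.std()
        z[sel] = (d - d.mean()) / (sd if sd > 0 else 1.0)
    top1 = np.argsort(-z, kind="stable")[:n_top]
    by_disp = {str(norm.gene_ids[i]) for i in top1 if np.isfinite(z[i])}

    # criterion 2: variance of Pearson residuals, NB trend dispersion
    counts = _counts_from_norm(norm)
    sf = norm.size_factors
    mean_g = (counts / sf[None, :]).mean(axis=1)
    mu = mean_g[:, None] * sf[None, :]
    resid_var_raw = ((counts - mu) ** 2 - mu).sum(axis=1)
    denom = (mu ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = np.where(denom > 0, resid_var_raw / denom, 0.0)
    alpha_hat = np.clip(alpha_hat, 1e-8, 100.0)
    ok = mean_g > 0
    trend_in = np.log(alpha_hat[ok])
    fitted = lowess(trend_in, np.log(mean_g[ok]), frac=0.5,
                    return_sorted=False)
    alpha_trend = np.full(norm.n_genes, np.median(alpha_hat[ok]))
    alpha_trend[ok] = np.exp(fitted)
    var_nb = mu + alpha_trend[:, None] * mu ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        pearson = np.where(var_nb > 0, (counts - mu) / np.sqrt(var_nb), 0.0)
    rvar = pearson.var(axis=1)
    rvar[~nonconst] = -np.inf
    top2 = np.argsort(-rvar, kind="stable")[:n_top]
    by_rvar = {str(norm.gene_ids[i]) for i in top2 if np.isfinite(rvar[i]) and rvar[i] > 0}

    return VariableGeneSet(by_dispersion=by_disp, by_residual_variance=by_rvar)
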