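"""Expression preprocessing: FPKM normalization, expressed-gene filtering,
MAD-based gene selection, sample PCA and sample-sample correlation.

The working transform for PCA, correlation heatmaps and networks is
log2(FPKM + 1) — a fixed, self-contained variance stabilization.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


def counts_to_fpkm(counts: ExpressionMatrix,
                   lengths: pd.Series | None = None,
                   libsizes: pd.Series | None = None) -> ExpressionMatrix:
    """FPKM[g, i] = counts[g, i] * 1e9 / (libsize_i * length_g).

    ``lengths`` (bp per gene) and ``libsizes`` (mapped fragments per sample)
    default to the ones attached to the matrix.
    """
    if counts.kind != "counts":
        raise ValueError("counts_to_fpkm needs a count matrix")
    lengths = counts.lengths if lengths is None else lengths
    libsizes = counts.libsizes if libsizes is None else libsizes
    if lengths is None or libsizes is None:
        raise ValueError("gene lengths and library sizes are required")
    missing_g = counts.genes.difference(lengths.index)
    if len(missing_g):
        raise ValueError(f"no length for gene(s): {list(missing_g)[:5]}")
    missing_s = counts.samples.difference(libsizes.index)
    if len(missing_s):
        raise ValueError(f"no library size for sample(s): {list(missing_s)[:5]}")
    lengths = lengths.loc[counts.genes].astype(float)
    libsizes = libsizes.loc[counts.samples].astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (libsizes <= 0).any():
        raise ValueError("library sizes must be positive")
    fpkm = counts.values * 1e9 / (libsizes.values[None, :] * lengths.values[:, None])
    return ExpressionMatrix(values=fpkm, meta=counts.meta, kind="fpkm",
                            lengths=lengths, libsizes=libsizes)


def filter_expressed(x: ExpressionMatrix, fpkm_min: float = 0.1,
                     frac_samples: float = 0.30) -> ExpressionMatrix:
    """Keep genes with FPKM strictly above ``fpkm_min`` in at least
    ``frac_samples`` of all samples (ceiling; 'at least 30%' is inclusive)."""
    if x.kind != "fpkm":
        raise ValueError("expressed-gene filter is defined on FPKM values")
    need = math.ceil(frac_samples * x.n_samples)
    n_above = (x.values > fpkm_min).sum(axis=1)
    keep = x.genes[n_above >= need]
    if len(keep) == 0:
        logger.warning("expressed-gene filter removed every gene")
    return x.subset_genes(keep)


def gene_mad(values: pd.DataFrame) -> pd.Series:
    """Per-gene median absolute deviation (no consistency constant — used
    for ranking only)."""
    med = values.median(axis=1)
    return (values.sub(med, axis=0)).abs().median(axis=1)


def select_top_mad(x: ExpressionMatrix, top_frac: float = 0.5) -> ExpressionMatrix:
    """Keep the ceil(top_frac * G) genes with the highest expression MAD.

    Ties at the cutoff break by gene-ID lexicographic order for determinism;
    the original gene order is preserved in the output.
    """
    if x.n_samples < 2:
        raise ValueError("MAD selection needs at least 2 samples")
    if not (0 < top_frac <= 1):
        raise ValueError("top_frac must lie in (0, 1]")
    k = math.ceil(top_frac * x.n_genes)
    mads = gene_mad(x.values)
    order = pd.DataFrame({"mad_": mads.to_numpy(), "gene_": list(mads.index)}) \
        .sort_values(["mad_", "gene_"], ascending=[False, True])
    chosen = set(order["gene_"].iloc[:k])
    keep = x.genes[[g in chosen for g in x.genes]]
    return x.subset_genes(keep)


def sample_pca(x: ExpressionMatrix, n_components: int | None = None
               ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on the gene-centered log2(FPKM + 1) matrix.

    Returns (coordinates samples x PCs, variance fractions). Uses the SVD of
    the centered matrix directly; fractions are non-increasing and sum to <= 1
    over the reported components.
    """
    if x.n_samples < 3:
        raise ValueError("PCA needs at least 3 samples")
    logx = x.log2()
    centered = logx.sub(logx.mean(axis=1), axis=0).to_numpy().T  # samples x genes
    if np.allclose(centered, 0):
        raise ValueError("constant expression matrix: PCA undefined")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    if n_components is None:
        n_components = min(10, len(s))
    coords = u[:, :n_components] * s[:n_components]
    var_frac = (s ** 2 / (s ** 2).sum())[:n_components]
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(coords, index=x.samples, columns=cols), var_frac


def pairwise_sample_correlation(x: ExpressionMatrix) -> pd.DataFrame:
    """Sample x sample Pearson correlation of log2(FPKM + 1) profiles.

    Constant samples yield undefined correlations reported as NaN.
    """
    logx = x.log2()
    with np.errstate(divide="ignore", invalid="ignore"):
        cor = np.corrcoef(logx.to_numpy().T)
    cor = pd.DataFrame(cor, index=x.samples, columns=x.samples)
    np.fill_diagonal(cor.values, 1.0)
    constant = logx.std(axis=0).to_numpy() == 0
    if constant.any():
        cor.iloc[constant, :] = np.nan
        cor.iloc[:, constant] = np.nan
    return cor
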