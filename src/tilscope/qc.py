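"""Per-cell quality control and ranked-GLSF normalization.

QC computes, for every cell, the number of detected genes, the total UMI
count and the mitochondrial count fraction, then removes cells with too few
detected genes (strictly fewer than ``min_genes``) or too high a
mitochondrial fraction (strictly above ``max_mito_fraction``).  Boundary
cells are kept.

Normalization is the ranked geometric library size factor (ranked GLSF):
DESeq-style median-of-ratios size factors computed not over all genes but
over the top-``top_n_rank`` genes by raw base mean.  Restricting the
reference panel to highly expressed genes reduces the influence of dropout
zeros, which would otherwise annihilate most genes' geometric means in
sparse UMI data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from tilscope.errors import EmptyAfterQcError, NoReferenceGenesError
from tilscope.tenx_io import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class QcThresholds:
    """Cell filtering thresholds.

    min_genes : keep cells detecting at least this many genes (default 500).
    max_mito_fraction : keep cells whose mitochondrial count fraction is at
        most this value (default 0.1).
    mito_prefix : gene-symbol prefix identifying mitochondrial genes,
        matched case-insensitively (default ``"MT-"``, human nomenclature).
    """

    min_genes: int = 500
    max_mito_fraction: float = 0.1
    mito_prefix: str = "MT-"

    def __post_init__(self):
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass
class NormalizationConfig:
    """Ranked-GLSF parameters.

    top_n_rank : number of top base-mean genes forming the reference panel
        (default 500; capped at the gene count).
    pseudocount : when True, add 1 to counts for the reference-panel
        geometric means and ratios so genes with zeros remain usable.
        Off by default.
    """

    top_n_rank: int = 500
    pseudocount: bool = False

    def __post_init__(self):
        if self.top_n_rank < 1:
            raise ValueError("top_n_rank must be >= 1")


def mito_gene_mask(matrix: CountMatrix, mito_prefix: str = "MT-") -> np.ndarray:
    """Boolean mask of genes whose symbol starts with the mito prefix."""
    prefix = mito_prefix.lower()
    return np.array(
        [str(s).lower().startswith(prefix) for s in matrix.gene_symbols], dtype=bool
    )


def compute_cell_qc(
    matrix: CountMatrix, thresholds: QcThresholds | None = None
) -> pd.DataFrame:
    """Per-cell QC statistics.

    Returns a DataFrame indexed by barcode with columns ``n_genes`` (genes
    with nonzero counts), ``n_umi`` (total counts) and ``mito_fraction``
    (mitochondrial counts / total counts, 0 for all-zero cells).
    """
    thresholds = thresholds or QcThresholds()
    counts = matrix.counts.tocsc()
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel()
    n_umi = np.asarray(counts.sum(axis=0)).ravel()
    mito = mito_gene_mask(matrix, thresholds.mito_prefix)
    mito_counts = np.asarray(counts[mito, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(n_umi > 0, mito_counts / np.maximum(n_umi, 1), 0.0)
    return pd.DataFrame(
        {
            "n_genes": n_genes.astype(int),
            "n_umi": n_umi.astype(int),
            "mito_fraction": mito_fraction,
        },
        index=pd.Index(matrix.barcodes, name="barcode"),
    )


def filter_cells(
    matrix: CountMatrix,
    stats: pd.DataFrame,
    thresholds: QcThresholds | None = None,
) -> CountMatrix:
    """Remove low-quality cells.

    A cell is kept iff ``n_genes >= min_genes`` **and**
    ``mito_fraction <= max_mito_fraction`` — removal thresholds are strict
    (a cell at exactly 500 genes or exactly 0.10 mito is kept).  Gene set
    and relative cell order are preserved.

    Raises
    ------
    EmptyAfterQcError
        If no cell survives.
    """
    thresholds = thresholds or QcThresholds()
    stats = stats.loc[matrix.barcodes]
    keep = (stats["n_genes"].to_numpy() >= thresholds.min_genes) & (
        stats["mito_fraction"].to_numpy() <= thresholds.max_mito_fraction
    )
    n_removed = int((~keep).sum())
    if not keep.any():
        raise EmptyAfterQcError(
            f"all {matrix.n_cells} cells removed by QC "
            f"(min_genes={thresholds.min_genes}, "
            f"max_mito={thresholds.max_mito_fraction})"
        )
    logger.info("QC: removed %d of %d cells", n_removed, matrix.n_cells)
    return matrix.subset_cells(np.flatnonzero(keep))


def compute_gene_stats(matrix, gene_names=None) -> pd.DataFrame:
    """Per-gene statistics on a genes x cells matrix (raw or normalized).

    base_mean : row mean.
    dispersion : Fano factor, population variance / mean (0 when mean is 0).
    coverage : number of cells with nonzero expression.
    """
    if isinstance(matrix, CountMatrix):
        gene_names = gene_names if gene_names is not None else matrix.gene_ids
        matrix = matrix.counts
    if sp.issparse(matrix):
        dense = np.asarray(matrix.todense(), dtype=float)
    else:
        dense = np.asarray(matrix, dtype=float)
    base_mean = dense.mean(axis=1)
    var = dense.var(axis=1)  # population variance (ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(base_mean > 0, var / np.maximum(base_mean, 1e-300), 0.0)
    coverage = (dense > 0).sum(axis=1)
    index = (
        pd.Index(gene_names, name="gene")
        if gene_names is not None
        else pd.RangeIndex(dense.shape[0], name="gene")
    )
    return pd.DataFrame(
        {"base_mean": base_mean, "dispersion": dispersion, "coverage": coverage},
        index=index,
    )


def ranked_glsf_normalize(
    matrix: CountMatrix, config: NormalizationConfig | None = None
):
    """Ranked geometric library size factor normalization.

    Procedure:

    1. rank genes by raw base mean (descending, ties broken by gene order)
       and take the top ``top_n_rank``;
    2. restrict to panel genes whose geometric mean over cells is positive,
       i.e. genes with no zero count in any cell (or all panel genes when
       ``pseudocount`` is on, computed on counts + 1);
    3. size factor of cell *j* = median over reference genes *g* of
       ``count[g, j] / geomean[g]``;
    4. normalized expression = counts divided cell-wise by size factors.

    Returns
    -------
    (normalized, size_factors)
        ``normalized`` is a dense float genes x cells array;
        ``size_factors`` a :class:`pandas.Series` indexed by barcode.

    Raises
    ------
    NoReferenceGenesError
        When no panel gene has a positive geometric mean; try a smaller
        ``top_n_rank`` or ``pseudocount=True``.
    """
    config = config or NormalizationConfig()
    counts = matrix.dense()
    n_genes, n_cells = counts.shape
    if n_cells < 1:
        raise ValueError("matrix must have at least one cell")

    base_mean = counts.mean(axis=1)
    top_n = min(config.top_n_rank, n_genes)
    # stable sort keeps gene order among ties
    order = np.argsort(-base_mean, kind="stable")
    panel = order[:top_n]

    ref_counts = counts[panel, :]
    if config.pseudocount:
        ref_counts = ref_counts + 1.0
        ref_mask = np.ones(len(panel), dtype=bool)
    else:
        ref_mask = (ref_counts > 0).all(axis=1)
    if not ref_mask.any():
        raise NoReferenceGenesError(
            "no gene in the top-ranked panel is nonzero in every cell; "
            "reduce top_n_rank or enable pseudocount mode"
        )
    ref = ref_counts[ref_mask, :]
    geomean = np.exp(np.log(ref).mean(axis=1))
    ratios = ref / geomean[:, None]
    size_factors = np.median(ratios, axis=0)
    normalized = counts / size_factors[None, :]
    logger.info(
        "ranked GLSF: %d reference genes of %d panel genes; "
        "size factors in [%.3g, %.3g]",
        int(ref_mask.sum()),
        top_n,
        size_factors.min(),
        size_factors.max(),
    )
    return normalized, pd.Series(
        size_factors, index=pd.Index(matrix.barcodes, name="barcode"), name="size_factor"
    )
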