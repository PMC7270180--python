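"""Cluster marker detection and marker-panel T-cell phenotyping.

Markers are scored per cluster by log2 fold-change of mean normalized
expression (in-cluster vs all other cells) with a Welch t-test and
Benjamini-Hochberg adjustment within each cluster.  Phenotypes are assigned
per cluster as the argmax of the mean z-scored expression of four canonical
CD8+ T-cell marker panels: cytotoxic, naive, exhausted and regulatory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from tilscope.errors import ConfigError, TilscopeError

logger = logging.getLogger(__name__)

#: Canonical marker panels (HGNC symbols; IFN-gamma is IFNG, PD-1 is PDCD1).
DEFAULT_PANELS = {
    "cytotoxic": ["PRF1", "GZMA", "GZMB", "IFNG"],
    "naive": ["CCR7", "LEF1", "TCF7", "IL7R"],
    "exhausted": ["BTLA", "CTLA4", "PDCD1", "LAG3"],
    "regulatory": ["FOXP3", "STAT3", "TNFRSF4", "TNFRSF9"],
}

#: Tie-break priority for equal panel scores.
PHENOTYPE_PRIORITY = ["cytotoxic", "naive", "exhausted", "regulatory"]

LFC_EPS = 1e-9  # pseudo-expression guarding log2 fold-changes of zero means


@dataclass
class PhenotypePanels:
    """Mapping phenotype name -> marker gene symbols."""

    panels: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_PANELS.items()})
    priority: list = field(default_factory=lambda: list(PHENOTYPE_PRIORITY))

    def __post_init__(self):
        for name, genes in self.panels.items():
            if not genes:
                raise ConfigError(f"panel {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ConfigError(f"panel {name!r} has duplicate genes")
        for name in self.panels:
            if name not in self.priority:
                self.priority.append(name)


@dataclass
class PhenotypeAssignment:
    """Cluster-level phenotype calls inherited by member cells.

    cluster_labels : dict cluster id -> phenotype.
    cluster_scores : DataFrame (cluster x phenotype) of mean panel z-scores.
    cell_labels : per-cell phenotype strings aligned with ``barcodes``.
    """

    cluster_labels: dict
    cluster_scores: pd.DataFrame
    cell_labels: np.ndarray
    barcodes: list | None = None


def marker_test(
    norm_matrix: np.ndarray,
    genes,
    labels: np.ndarray,
    eps: float = LFC_EPS,
) -> pd.DataFrame:
    """Per-cluster marker statistics.

    For every cluster c and gene g computes
    ``lfc = log2((mean_in + eps) / (mean_out + eps))``, a Welch (unequal
    variance) two-sample t-test of in-cluster vs all other cells, and
    Benjamini-Hochberg adjusted p-values within each cluster.

    Degenerate conventions: when both groups have zero variance, p = 1.0 if
    the means are equal, else 0.0.  Clusters with fewer than 2 cells get
    missing p-values (logged).
    """
    X = np.asarray(norm_matrix, dtype=float)
    labels = np.asarray(labels)
    clusters = sorted(pd.unique(labels))
    if len(clusters) < 2:
        raise TilscopeError("marker_test needs at least 2 clusters")
    frames = []
    for c in clusters:
        mask = labels == c
        inn, out = X[:, mask], X[:, ~mask]
        mean_in, mean_out = inn.mean(axis=1), out.mean(axis=1)
        lfc = np.log2((mean_in + eps) / (mean_out + eps))
        if mask.sum() < 2 or (~mask).sum() < 2:
            logger.warning("cluster %s has <2 cells; p-values missing", c)
            pvals = np.full(X.shape[0], np.nan)
            padj = pvals
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                _, pvals = sps.ttest_ind(inn, out, axis=1, equal_var=False)
            var_in = inn.var(axis=1, ddof=1)
            var_out = out.var(axis=1, ddof=1)
            degenerate = (var_in == 0) & (var_out == 0)
            pvals = np.where(
                degenerate, np.where(mean_in == mean_out, 1.0, 0.0), pvals
            )
            pvals = np.nan_to_num(pvals, nan=1.0)
            padj = multipletests(pvals, method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "cluster": c,
                    "gene": list(genes),
                    "mean_in": mean_in,
                    "mean_out": mean_out,
                    "lfc": lfc,
                    "pvalue": pvals,
                    "padj": padj,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def score_phenotypes(
    norm_matrix: np.ndarray,
    genes,
    labels: np.ndarray,
    panels: PhenotypePanels | None = None,
    barcodes=None,
) -> PhenotypeAssignment:
    """Assign one of the four phenotypes to each cluster.

    Each gene is z-scored across cells (population SD; constant genes get
    z = 0 with a warning).  A cluster's score for a phenotype is the mean z
    over the panel's genes and the cluster's cells; the label is the argmax,
    ties resolved by the fixed priority order and logged.

    Raises
    ------
    TilscopeError
        If any phenotype has no panel gene present in the matrix (all
        missing genes listed), or no panel gene is found at all.
    """
    panels = panels or PhenotypePanels()
    X = np.asarray(norm_matrix, dtype=float)
    gene_pos = {g: i for i, g in enumerate(genes)}

    rows_by_pheno = {}
    missing_report = {}
    for name, panel in panels.panels.items():
        present = [gene_pos[g] for g in panel if g in gene_pos]
        if not present:
            missing_report[name] = panel
        rows_by_pheno[name] = present
    if len(missing_report) == len(panels.panels):
        raise TilscopeError("no panel gene found in the matrix at all")
    if missing_report:
        raise TilscopeError(
            f"phenotypes with no panel gene present: {missing_report}"
        )

    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    constant = sd.ravel() == 0
    if constant.any():
        logger.warning("%d constant genes get z=0", int(constant.sum()))
    z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    labels = np.asarray(labels)
    clusters = sorted(pd.unique(labels))
    phenos = list(panels.panels)
    scores = pd.DataFrame(index=pd.Index(clusters, name="cluster"), columns=phenos, dtype=float)
    for c in clusters:
        cell_mask = labels == c
        for name in phenos:
            rows = rows_by_pheno[name]
            scores.loc[c, name] = float(z[np.ix_(rows, np.flatnonzero(cell_mask))].mean())

    cluster_labels = {}
    candidates = [p for p in panels.priority if p in panels.panels]
    for c in clusters:
        row = scores.loc[c]
        best = max(candidates, key=lambda p: (row[p], -panels.priority.index(p)))
        tied = [p for p in phenos if row[p] == row[best]]
        if len(tied) > 1:
            logger.warning(
                "cluster %s: tied phenotype scores %s; priority picks %r", c, tied, best
            )
        cluster_labels[c] = best

    cell_labels = np.array([cluster_labels[c] for c in labels], dtype=object)
    return PhenotypeAssignment(
        cluster_labels=cluster_labels,
        cluster_scores=scores,
        cell_labels=cell_labels,
        barcodes=list(barcodes) if barcodes is not None else None,
    )


def phenotype_proportions(
    assignment: PhenotypeAssignment,
    sample_of_cell: dict,
    group_of_sample: dict | None = None,
    phenotypes=None,
) -> tuple:
    """Per-sample (and optionally per-group) phenotype proportions.

    Parameters
    ----------
    assignment : PhenotypeAssignment
        Must carry barcodes.
    sample_of_cell : dict barcode -> sample name; every cell must be mapped.
    group_of_sample : dict sample -> group, optional.

    Returns
    -------
    (per_sample, per_group)
        DataFrames of proportions (rows sum to 1); ``per_group`` is None when
        no group map is given.  Group means are unweighted means of
        per-sample proportions.
    """
    if assignment.barcodes is None:
        raise TilscopeError("assignment carries no barcodes")
    phenotypes = list(phenotypes) if phenotypes is not None else list(PHENOTYPE_PRIORITY)
    records = []
    for barcode, label in zip(assignment.barcodes, assignment.cell_labels):
        if barcode not in sample_of_cell:
            raise TilscopeError(f"cell {barcode!r} is not mapped to a sample")
        records.append((sample_of_cell[barcode], label))
    df = pd.DataFrame(records, columns=["sample", "phenotype"])
    counts = (
        df.groupby(["sample", "phenotype"]).size().unstack(fill_value=0)
    )
    for p in phenotypes:
        if p not in counts.columns:
            counts[p] = 0
    counts = counts[phenotypes]
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise TilscopeError(f"samples with no cells: {empty}")
    per_sample = counts.div(totals, axis=0)
    per_group = None
    if group_of_sample is not None:
        per_group = per_sample.groupby(
            [group_of_sample[s] for s in per_sample.index]
        ).mean()
        per_group.index.name = "group"
    return per_sample, per_group


@dataclass
class ProportionComparison:
    """Two-group comparison of a phenotype's abundance.

    pooled_* : two-proportion z-test on cells pooled within each group.
    per_sample_* : Welch t-test on per-sample proportions (None when a group
        has fewer than 2 samples).
    """

    pooled_z: float
    pooled_p: float
    per_sample_t: float | None
    per_sample_p: float | None
    group_counts: tuple


def compare_proportions(
    counts_a,
    counts_b,
    per_sample_props_a=None,
    per_sample_props_b=None,
) -> ProportionComparison:
    """Compare a phenotype's abundance between two groups.

    Parameters
    ----------
    counts_a, counts_b : (hits, total)
        Pooled cell counts per group: cells of the phenotype and total cells.
    per_sample_props_a, per_sample_props_b : sequences of float, optional
        Per-sample proportions, for the companion Welch t-test (reported as
        not computable when either group has < 2 samples).
    """
    ka, na = counts_a
    kb, nb = counts_b
    if na == 0 or nb == 0:
        raise TilscopeError("zero cells in a group")
    if ka / na == kb / nb:
        z, p = 0.0, 1.0  # identical pooled proportions (incl. 0/0 variance edge)
    else:
        z, p = proportions_ztest([ka, kb], [na, nb])
    t_stat = t_p = None
    if (
        per_sample_props_a is not None
        and per_sample_props_b is not None
        and len(per_sample_props_a) >= 2
        and len(per_sample_props_b) >= 2
    ):
        a = np.asarray(per_sample_props_a, dtype=float)
        b = np.asarray(per_sample_props_b, dtype=float)
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            t_stat, t_p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            t_stat, t_p = sps.ttest_ind(a, b, equal_var=False)
            t_stat, t_p = float(t_stat), float(t_p)
    return ProportionComparison(
        pooled_z=float(z),
        pooled_p=float(p),
        per_sample_t=t_stat,
        per_sample_p=t_p,
        group_counts=((ka, na), (kb, nb)),
    )
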