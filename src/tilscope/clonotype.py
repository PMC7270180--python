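"""Clonotype construction and repertoire clonality statistics.

A clonotype is the set of cells (barcodes) sharing identical productive
TRA/TRB CDR3 amino-acid sequences.  The default clonotype key is the sorted,
semicolon-joined set of ``chain:CDR3aa`` tokens from a cell's productive
contigs, which is stable across upstream runs; the upstream
``raw_clonotype_id`` can be used instead for fidelity.

Frequency classes follow the repertoire-plot convention: singletons are
clonotypes seen in exactly one cell, doubletons in exactly two; "top10" are
the ten most frequent clonotypes (with at least three cells), and "other"
collects the remaining tripleton-or-higher clonotypes.  Cells (barcodes),
not reads, are the default unit of counting; a UMI-weighted mode exists.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from tilscope.errors import TilscopeError
from tilscope.tenx_io import VdjTable

logger = logging.getLogger(__name__)


@dataclass
class ClonotypeSummary:
    """Per-clonotype frequencies, ranks and classes.

    table : DataFrame with columns ``key``, ``frequency``, ``rank`` (1 = most
        frequent, ties broken by key order) and ``freq_class`` in
        {top10, other, doubleton, singleton}.
    members : dict key -> list of member barcodes.
    n_cells : number of cells with >= 1 productive chain.
    n_excluded : barcodes dropped for lacking a productive TRA/TRB contig.
    """

    table: pd.DataFrame
    members: dict
    n_cells: int
    n_excluded: int

    @property
    def n_clonotypes(self) -> int:
        return len(self.table)

    @property
    def frequencies(self) -> np.ndarray:
        return self.table["frequency"].to_numpy()


@dataclass
class ClonalityReport:
    """Headline clonality statistics for one sample (percent scale)."""

    top10_share: float
    upper_quintile_clonotypes: int
    n_clonotypes: int
    n_singletons: int
    n_doubletons: int
    n_cells: int


def _classify(frequency: int, rank: int) -> str:
    if frequency == 1:
        return "singleton"
    if frequency == 2:
        return "doubleton"
    if rank <= 10:
        return "top10"
    return "other"


def build_clonotypes(
    vdj: VdjTable, mode: str = "cdr3_pair", weight: str = "cells"
) -> ClonotypeSummary:
    """Group cells into clonotypes.

    Parameters
    ----------
    vdj : VdjTable
    mode : {"cdr3_pair", "raw_id"}
        ``cdr3_pair`` (default) keys each cell by its sorted set of
        productive ``chain:CDR3aa`` tokens (cells with multiple productive
        chains of one locus keep all tokens).  ``raw_id`` uses the upstream
        clonotype id.
    weight : {"cells", "umis"}
        Unit of the frequency column: member cells (default) or summed UMIs
        of the members' productive contigs.

    Cells with no productive TRA/TRB contig are excluded and counted.
    """
    if weight not in ("cells", "umis"):
        raise TilscopeError(f"unknown weight {weight!r}")
    df = vdj.df
    usable = df[
        df["productive"] & df["chain"].isin(["TRA", "TRB"]) & (df["cdr3_aa"] != "")
    ]
    all_barcodes = set(df["barcode"])
    keys = {}
    if mode == "cdr3_pair":
        for barcode, grp in usable.groupby("barcode", sort=False):
            tokens = sorted(
                f"{chain}:{cdr3}"
                for chain, cdr3 in zip(grp["chain"], grp["cdr3_aa"])
            )
            keys[barcode] = ";".join(tokens)
    elif mode == "raw_id":
        with_id = usable[usable["raw_clonotype_id"] != ""]
        if with_id.empty:
            raise TilscopeError(
                "mode='raw_id' but no raw_clonotype_id present; use cdr3_pair"
            )
        for barcode, grp in with_id.groupby("barcode", sort=False):
            keys[barcode] = grp["raw_clonotype_id"].iloc[0]
    else:
        raise TilscopeError(f"unknown clonotype mode {mode!r}")

    n_excluded = len(all_barcodes) - len(keys)
    if n_excluded:
        logger.info("clonotypes: %d barcodes lack a productive chain", n_excluded)

    members = {}
    for barcode, key in keys.items():
        members.setdefault(key, []).append(barcode)
    if weight == "cells":
        freq = {k: len(v) for k, v in members.items()}
        n_units = len(keys)
    else:
        umis_of_cell = usable.groupby("barcode")["umis"].sum().to_dict()
        freq = {
            k: int(sum(umis_of_cell.get(b, 0) for b in v))
            for k, v in members.items()
        }
        n_units = int(sum(freq.values()))
    ordered = sorted(freq, key=lambda k: (-freq[k], k))
    table = pd.DataFrame(
        {
            "key": ordered,
            "frequency": [freq[k] for k in ordered],
            "rank": np.arange(1, len(ordered) + 1),
        }
    )
    table["freq_class"] = [
        _classify(f, r) for f, r in zip(table["frequency"], table["rank"])
    ]
    return ClonotypeSummary(
        table=table,
        members={k: sorted(members[k]) for k in ordered},
        n_cells=n_units,
        n_excluded=n_excluded,
    )


def frequency_partition(summary: ClonotypeSummary) -> pd.DataFrame:
    """Percent of cells per repertoire-plot category.

    Categories: each of the ten most frequent clonotypes with >= 3 cells
    individually (``clonotype_<rank>``; absent when there is no such
    clonotype at that rank — no zero padding), ``other`` (frequency >= 3,
    rank > 10), ``doubletons`` and ``singletons``.  Percentages sum to 100.
    """
    total = summary.n_cells
    rows = []
    t = summary.table
    for _, rec in t[t["freq_class"] == "top10"].iterrows():
        rows.append((f"clonotype_{rec['rank']}", rec["frequency"]))
    rows.append(("other", int(t.loc[t["freq_class"] == "other", "frequency"].sum())))
    rows.append(
        ("doubletons", int(t.loc[t["freq_class"] == "doubleton", "frequency"].sum()))
    )
    rows.append(
        ("singletons", int(t.loc[t["freq_class"] == "singleton", "frequency"].sum()))
    )
    out = pd.DataFrame(rows, columns=["category", "n_cells"])
    out["percent"] = 100.0 * out["n_cells"] / total if total else 0.0
    return out


def top_n_share(summary: ClonotypeSummary, n: int = 10) -> float:
    """Percent of cells belonging to the ``n`` most frequent clonotypes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if summary.n_cells == 0:
        return 0.0
    top = summary.table.nsmallest(n, "rank")["frequency"].sum()
    return 100.0 * float(top) / summary.n_cells


def upper_quintile_clonotypes(summary: ClonotypeSummary) -> int:
    """Distinct clonotypes covering the top 20% of cells by clonal expansion.

    Clonotypes are taken in rank order (descending frequency, ties by key)
    and accumulated until the running cell total reaches 20% of all cells;
    the clonotype crossing the boundary is included.
    """
    if summary.n_cells < 1:
        raise TilscopeError("upper_quintile_clonotypes needs >= 1 cell")
    quintile = 0.2 * summary.n_cells
    cum = 0
    for i, f in enumerate(summary.frequencies, start=1):
        cum += int(f)
        if cum >= quintile:
            return i
    return summary.n_clonotypes


def clonality_report(summary: ClonotypeSummary) -> ClonalityReport:
    """Assemble the headline clonality statistics for one sample."""
    t = summary.table
    return ClonalityReport(
        top10_share=top_n_share(summary, 10),
        upper_quintile_clonotypes=upper_quintile_clonotypes(summary),
        n_clonotypes=summary.n_clonotypes,
        n_singletons=int((t["freq_class"] == "singleton").sum()),
        n_doubletons=int((t["freq_class"] == "doubleton").sum()),
        n_cells=summary.n_cells,
    )


def link_clonotypes_to_phenotypes(
    summary: ClonotypeSummary,
    assignment,
    mapping,
    top_n: int = 10,
    span_threshold: float = 0.2,
) -> pd.DataFrame:
    """Phenotype composition of the most expanded clonotypes.

    For each of the ``top_n`` ranked clonotypes, member barcodes are carried
    through the VDJ->expression barcode mapping and counted per phenotype.  A
    clonotype *spans* phenotypes when at least two phenotypes each hold at
    least ``span_threshold`` of its matched cells (descriptive annotation).

    Parameters
    ----------
    summary : ClonotypeSummary
    assignment : tilscope.phenotype.PhenotypeAssignment
        Must carry barcodes.
    mapping : tilscope.tenx_io.BarcodeMap
        As returned by ``harmonize_barcodes(matrix, vdj)``.
    """
    pheno_of_expr = dict(zip(assignment.barcodes, assignment.cell_labels))
    vdj_to_expr = {v: k for k, v in mapping.matched.items()}
    phenotypes = sorted(set(assignment.cell_labels))
    rows = []
    for _, rec in summary.table.nsmallest(top_n, "rank").iterrows():
        counts = {p: 0 for p in phenotypes}
        unmatched = 0
        for barcode in summary.members[rec["key"]]:
            expr = vdj_to_expr.get(barcode)
            if expr is None or expr not in pheno_of_expr:
                unmatched += 1
            else:
                counts[pheno_of_expr[expr]] += 1
        matched = sum(counts.values())
        spanning = (
            matched > 0
            and sum(1 for v in counts.values() if v / matched >= span_threshold) >= 2
        )
        rows.append(
            {
                "key": rec["key"],
                "rank": rec["rank"],
                "frequency": rec["frequency"],
                "n_matched": matched,
                "n_unmatched": unmatched,
                "spanning": spanning,
                **counts,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RichnessComparison:
    """Two-group comparison of per-sample clonotype counts."""

    mean_a: float
    mean_b: float
    t_stat: float | None
    p_value: float | None
    computable: bool


def compare_clonotype_richness(group_a, group_b) -> RichnessComparison:
    """Compare clonotype richness (clonotypes per sample) between groups.

    Accepts sequences of ClonotypeSummary or of integer clonotype counts.
    Means are always returned; the Welch t-test requires >= 2 samples per
    group and is otherwise flagged not computable.
    """

    def _counts(group):
        return [
            g.n_clonotypes if isinstance(g, ClonotypeSummary) else int(g)
            for g in group
        ]

    a, b = _counts(group_a), _counts(group_b)
    if not a or not b:
        raise TilscopeError("each group needs >= 1 sample for means")
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    if len(a) < 2 or len(b) < 2:
        return RichnessComparison(mean_a, mean_b, None, None, False)
    av, bv = np.var(a, ddof=1), np.var(b, ddof=1)
    if av == 0 and bv == 0:
        t, p = (0.0, 1.0) if mean_a == mean_b else (math.inf, 0.0)
    else:
        t, p = sps.ttest_ind(a, b, equal_var=False)
        t, p = float(t), float(p)
    return RichnessComparison(mean_a, mean_b, t, p, True)
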