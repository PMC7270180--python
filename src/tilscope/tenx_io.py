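"""Readers and writers for the three external table formats.

Supported formats:

* **Expression triplet** — a directory in the 10x Genomics convention:
  ``matrix.mtx`` (Matrix Market coordinate, genes x cells),
  ``barcodes.tsv`` (one cell barcode per line) and ``features.tsv``
  (column 1 = gene id, column 2 = gene symbol).  Each file may be plain or
  gzipped; compression is sniffed from magic bytes, never the extension.
* **VDJ contig annotations** — the CSV dialect of
  ``filtered_contig_annotations.csv`` produced by upstream VDJ assembly
  (one row per assembled contig, keyed by cell barcode).
* **TCR-antigen association table** — a CSV in the McPAS-TCR dialect
  (``CDR3.alpha.aa``, ``CDR3.beta.aa``, ``Antigen.protein``, ...), with a
  configurable column map for other curated databases.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from tilscope.errors import (
    InconsistentTripletError,
    MissingComponentError,
    SchemaError,
)

logger = logging.getLogger(__name__)

GZIP_MAGIC = b"\x1f\x8b"

#: Canonical VdjTable column order.
VDJ_COLUMNS = [
    "barcode",
    "is_cell",
    "high_confidence",
    "chain",
    "v_gene",
    "d_gene",
    "j_gene",
    "cdr3_aa",
    "cdr3_nt",
    "reads",
    "umis",
    "productive",
    "raw_clonotype_id",
]

#: Default antigen-DB column map (internal name -> McPAS-TCR header).
MCPAS_COLUMN_MAP = {
    "cdr3_alpha_aa": "CDR3.alpha.aa",
    "cdr3_beta_aa": "CDR3.beta.aa",
    "antigen_protein": "Antigen.protein",
    "epitope_peptide": "Epitope.peptide",
    "pathology": "Pathology",
    "category": "Category",
}

ANTIGEN_COLUMNS = list(MCPAS_COLUMN_MAP)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Sparse genes x cells matrix of non-negative integer UMI counts.

    Attributes
    ----------
    gene_ids : list of str
        Unique feature identifiers (e.g. Ensembl ids), in file order.
    gene_symbols : list of str
        Display names aligned with ``gene_ids`` (e.g. HGNC symbols).
    barcodes : list of str
        Unique cell barcodes, in file order.
    counts : scipy.sparse.csr_matrix
        Counts with shape ``(len(gene_ids), len(barcodes))``.
    """

    gene_ids: list
    gene_symbols: list
    barcodes: list
    counts: sp.csr_matrix

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.validate()

    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_ids) or n_cells != len(self.barcodes):
            raise InconsistentTripletError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} barcodes"
            )
        if len(self.gene_symbols) != len(self.gene_ids):
            raise InconsistentTripletError("gene_symbols misaligned with gene_ids")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise InconsistentTripletError("barcodes are not unique")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InconsistentTripletError("gene_ids are not unique")
        data = self.counts.data
        if data.size and (data.min() < 0 or np.any(data != np.round(data))):
            raise InconsistentTripletError("counts must be non-negative integers")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        """Dense float64 copy of the counts (genes x cells)."""
        return np.asarray(self.counts.todense(), dtype=float)

    def subset_cells(self, index) -> "CountMatrix":
        """New CountMatrix restricted to the cells at ``index`` (order kept)."""
        index = np.asarray(index)
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            gene_symbols=list(self.gene_symbols),
            barcodes=[self.barcodes[i] for i in index],
            counts=self.counts[:, index].tocsr(),
        )


@dataclass
class VdjTable:
    """Per-contig VDJ records as a normalized :class:`pandas.DataFrame`.

    Columns are :data:`VDJ_COLUMNS`; chains outside {TRA, TRB} are mapped to
    ``"other"`` but the rows are retained.
    """

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in VDJ_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"VdjTable missing columns: {missing}")
        self.df = self.df[VDJ_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def barcodes(self) -> list:
        return list(self.df["barcode"].unique())


@dataclass
class AntigenDb:
    """Curated CDR3 -> antigen association records.

    Rows lacking both CDR3 chains are dropped at load time; ``n_dropped``
    records how many.
    """

    df: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self):
        missing = [c for c in ANTIGEN_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"AntigenDb missing columns: {missing}")
        self.df = self.df[ANTIGEN_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class BarcodeMap:
    """Result of :func:`harmonize_barcodes`.

    ``matched`` maps expression-side barcodes to VDJ-side barcodes (original
    spellings).  Unmatched counts are reported for both sides; zero matches is
    a warning-level outcome, not an error.
    """

    matched: dict
    unmatched_expression: int
    unmatched_vdj: int

    @property
    def n_matched(self) -> int:
        return len(self.matched)

    def inverse(self) -> "BarcodeMap":
        return BarcodeMap(
            matched={v: k for k, v in self.matched.items()},
            unmatched_expression=self.unmatched_vdj,
            unmatched_vdj=self.unmatched_expression,
        )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _open_maybe_gzip(path: Path, mode: str = "rb"):
    """Open a file, transparently decompressing if it starts with gzip magic."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == GZIP_MAGIC:
        return gzip.open(path, mode)
    return open(path, mode)


def _find_component(directory: Path, stems: tuple) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            candidate = directory / name
            if candidate.exists():
                return candidate
    raise MissingComponentError(
        f"no file matching {stems} (plain or .gz) in {directory}"
    )


# ---------------------------------------------------------------------------
# expression triplet
# ---------------------------------------------------------------------------


def read_expression_triplet(directory) -> CountMatrix:
    """Read a 10x-style expression triplet directory into a CountMatrix.

    Expects ``matrix.mtx``, ``barcodes.tsv`` and ``features.tsv`` (or
    ``genes.tsv``), each optionally gzipped.  Feature-table order becomes gene
    order; barcode order becomes cell order.

    Raises
    ------
    MissingComponentError
        If any of the three component files is absent.
    InconsistentTripletError
        If the matrix header dimensions disagree with the table lengths.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise MissingComponentError(f"not a directory: {directory}")
    mtx_path = _find_component(directory, ("matrix.mtx",))
    bc_path = _find_component(directory, ("barcodes.tsv",))
    feat_path = _find_component(directory, ("features.tsv", "genes.tsv"))

    with _open_maybe_gzip(mtx_path) as fh:
        mat = scipy.io.mmread(io.BytesIO(fh.read()))
    with _open_maybe_gzip(bc_path, "rb") as fh:
        barcodes = [l.strip() for l in fh.read().decode().splitlines() if l.strip()]
    with _open_maybe_gzip(feat_path, "rb") as fh:
        text = fh.read().decode()
    feat_rows = [l.split("\t") for l in text.splitlines() if l.strip()]
    gene_ids = [r[0] for r in feat_rows]
    gene_symbols = [r[1] if len(r) > 1 else r[0] for r in feat_rows]

    mat = sp.coo_matrix(mat)
    if mat.shape != (len(gene_ids), len(barcodes)):
        raise InconsistentTripletError(
            f"matrix header {mat.shape} inconsistent with "
            f"{len(gene_ids)} features and {len(barcodes)} barcodes"
        )
    return CountMatrix(
        gene_ids=gene_ids,
        gene_symbols=gene_symbols,
        barcodes=barcodes,
        counts=mat.tocsr(),
    )


def write_expression_triplet(matrix: CountMatrix, directory) -> None:
    """Write a CountMatrix as an uncompressed expression triplet.

    The output is readable by :func:`read_expression_triplet` and reproduces
    the matrix entry-wise (integer Matrix Market coordinate format).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = matrix.counts.tocoo()
    with open(directory / "matrix.mtx", "wb") as fh:
        scipy.io.mmwrite(fh, coo, field="integer")
    (directory / "barcodes.tsv").write_text(
        "".join(b + "\n" for b in matrix.barcodes)
    )
    (directory / "features.tsv").write_text(
        "".join(
            f"{gid}\t{sym}\tGene Expression\n"
            for gid, sym in zip(matrix.gene_ids, matrix.gene_symbols)
        )
    )


# ---------------------------------------------------------------------------
# VDJ contig annotations
# ---------------------------------------------------------------------------

_TRUE_STRINGS = {"true", "1", "yes"}


def _parse_bool(value) -> bool:
    # "None" (upstream's marker for an uncallable field) parses as False:
    # a chain whose productivity could not be determined must not seed a
    # clonotype.
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if pd.isna(value):
        return False
    return str(value).strip().lower() in _TRUE_STRINGS


def read_contig_annotations(path) -> VdjTable:
    """Read a ``filtered_contig_annotations.csv``-style table.

    Mandatory columns: ``barcode``, ``chain``, ``cdr3``, ``productive``.
    Textual booleans ("True"/"true"/"TRUE") are parsed; the literal "None"
    parses as False.  Rows with a chain outside {TRA, TRB} are retained with
    ``chain="other"``.

    Raises
    ------
    SchemaError
        Naming the first mandatory column that is missing.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("barcode", "chain", "cdr3", "productive"):
        if col not in df.columns:
            raise SchemaError(f"contig annotation table missing column '{col}'")

    def _get(col, default=""):
        return df[col] if col in df.columns else pd.Series([default] * len(df))

    def _int(col):
        raw = _get(col, "0").replace("", "0")
        return pd.to_numeric(raw, errors="coerce").fillna(0).astype(int)

    chain = df["chain"].where(df["chain"].isin(["TRA", "TRB"]), "other")
    out = pd.DataFrame(
        {
            "barcode": df["barcode"],
            "is_cell": _get("is_cell", "True").map(_parse_bool),
            "high_confidence": _get("high_confidence", "True").map(_parse_bool),
            "chain": chain,
            "v_gene": _get("v_gene"),
            "d_gene": _get("d_gene"),
            "j_gene": _get("j_gene"),
            "cdr3_aa": df["cdr3"].replace("None", ""),
            "cdr3_nt": _get("cdr3_nt").replace("None", ""),
            "reads": _int("reads"),
            "umis": _int("umis"),
            "productive": df["productive"].map(_parse_bool),
            "raw_clonotype_id": _get("raw_clonotype_id").replace("None", ""),
        }
    )
    return VdjTable(out)


def write_contig_annotations(vdj: VdjTable, path) -> None:
    """Write a VdjTable back to the upstream CSV dialect."""
    df = vdj.df.rename(columns={"cdr3_aa": "cdr3"})
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# antigen DB
# ---------------------------------------------------------------------------


def read_antigen_db(path, column_map: dict | None = None) -> AntigenDb:
    """Read a curated TCR-antigen table (McPAS-TCR header dialect by default).

    Parameters
    ----------
    path : path-like
        CSV file with at least the CDR3 alpha/beta, antigen and pathology
        columns named by ``column_map``.
    column_map : dict, optional
        Mapping internal name -> file header, defaulting to
        :data:`MCPAS_COLUMN_MAP`.

    Rows lacking both CDR3 chains are dropped; the dropped count is logged
    and stored on the returned :class:`AntigenDb`.
    """
    cmap = dict(MCPAS_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [src for src in cmap.values() if src not in df.columns]
    if missing:
        raise SchemaError(f"antigen DB missing columns: {missing}")
    out = pd.DataFrame({internal: df[src] for internal, src in cmap.items()})
    has_cdr3 = (out["cdr3_alpha_aa"].str.strip() != "") | (
        out["cdr3_beta_aa"].str.strip() != ""
    )
    n_dropped = int((~has_cdr3).sum())
    if n_dropped:
        logger.info("antigen DB: dropped %d rows lacking both CDR3 chains", n_dropped)
    return AntigenDb(df=out[has_cdr3].reset_index(drop=True), n_dropped=n_dropped)


def write_antigen_db(db: AntigenDb, path, column_map: dict | None = None) -> None:
    """Write an AntigenDb using the default (or given) header dialect."""
    cmap = dict(MCPAS_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    db.df.rename(columns=cmap).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# barcode harmonization
# ---------------------------------------------------------------------------

_GEM_SUFFIX = re.compile(r"-\d+$")


def canonical_barcode(barcode: str) -> str:
    """Strip a trailing ``-<digits>`` GEM-well suffix from a barcode."""
    return _GEM_SUFFIX.sub("", barcode)


def harmonize_barcodes(matrix, vdj) -> BarcodeMap:
    """Match expression barcodes to VDJ barcodes after suffix canonicalization.

    Both gene-expression and VDJ libraries tag transcripts of one droplet
    with the same GEM barcode, but the two pipelines may or may not append a
    ``-<well>`` suffix.  Matching is on the canonical (suffix-stripped) form.

    Parameters
    ----------
    matrix : CountMatrix or sequence of str
        Expression side (cells), or a bare barcode list.
    vdj : VdjTable or sequence of str
        VDJ side (distinct contig barcodes), or a bare barcode list.

    Returns
    -------
    BarcodeMap
        Matched pairs (original spellings) and unmatched counts per side.
        Zero matches logs a warning but is not an error.
    """
    left = matrix.barcodes if hasattr(matrix, "barcodes") else list(matrix)
    right = vdj.barcodes if hasattr(vdj, "barcodes") else list(vdj)

    def _index(barcodes, side):
        idx = {}
        for b in barcodes:
            canon = canonical_barcode(b)
            if canon in idx:
                logger.warning("%s side: canonical barcode collision for %r", side, b)
                continue
            idx[canon] = b
        return idx

    left_idx = _index(left, "expression")
    right_idx = _index(right, "vdj")
    shared = sorted(set(left_idx) & set(right_idx))
    matched = {left_idx[c]: right_idx[c] for c in shared}
    result = BarcodeMap(
        matched=matched,
        unmatched_expression=len(left) - len(matched),
        unmatched_vdj=len(right) - len(matched),
    )
    if not matched:
        logger.warning("harmonize_barcodes: zero matches between sides")
    return result
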