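"""Synthetic paired expression + VDJ + antigen-DB datasets with ground truth.

The generator emulates the statistical structure the analysis pipeline
consumes, so every stage is testable without downloading data:

* UMI counts drawn negative-binomial per gene class — a large background
  block, a small high-expression housekeeping block (the reference panel for
  size factors), the sixteen phenotype marker-panel genes, and mitochondrial
  genes;
* planted phenotype clusters: each cell gets one of the four T-cell
  phenotypes and its panel genes' means are multiplied by the marker effect
  size (default 8-fold);
* mitochondrial fractions drawn from a Beta distribution and converted to
  counts, with an optional fraction of deliberately low-quality cells that
  strictly violate the QC thresholds;
* Zipf-distributed clonal expansion: paired TRA/TRB CDR3 amino-acid
  sequences assigned to cells from a rank-frequency law with per-group
  exponent (high exponent = expanded repertoire, low = flat);
* an antigen database containing exact and edit-perturbed copies of the top
  clonotypes' CDR3s plus decoy records.

All randomness flows from a single seed through spawned generator streams;
identical configuration and seed give identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from tilscope.errors import ConfigError
from tilscope.phenotype import DEFAULT_PANELS, PHENOTYPE_PRIORITY
from tilscope.tenx_io import ANTIGEN_COLUMNS, AntigenDb, CountMatrix, VdjTable, VDJ_COLUMNS

logger = logging.getLogger(__name__)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
NUCLEOTIDES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    Two groups of samples are generated (an "expanded" and a "flat"
    repertoire group by default, mirroring immunocompetent vs transplant
    cohorts).  See the methods note for the rationale behind the count-model
    defaults.
    """

    n_cells: int = 400
    n_samples_per_group: int = 3
    group_names: tuple = ("SCC", "TSCC")
    #: Zipf rank-frequency exponent per group (aligned with group_names).
    zipf_exponent: tuple = (1.5, 0.2)
    #: phenotype mixture, aligned with PHENOTYPE_PRIORITY order.
    phenotype_proportions: tuple = (0.25, 0.25, 0.25, 0.25)
    marker_effect_size: float = 8.0
    panel_base_mean: float = 4.0
    panel_nb_size: float = 10.0
    n_background_genes: int = 1000
    background_mean: float = 2.0
    background_nb_size: float = 8.0
    n_housekeeping_genes: int = 50
    housekeeping_mean: float = 50.0
    housekeeping_nb_size: float = 100.0
    n_mito_genes: int = 13
    #: Beta(a, b) for per-cell target mitochondrial fraction.
    mito_beta: tuple = (2.0, 38.0)
    qc_fail_fraction: float = 0.0
    vdj_fraction: float = 0.9
    #: fraction of VDJ cells whose contigs are all non-productive.
    nonproductive_cell_fraction: float = 0.02
    #: probability a top clonotype gets an exact DB entry (else perturbed).
    db_exact_fraction: float = 0.5
    #: edit distances planted for perturbed DB entries.
    planted_distances: tuple = (1, 2, 3)
    n_db_decoys: int = 20
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.phenotype_proportions) - 1.0) > 1e-9:
            raise ConfigError("phenotype_proportions must sum to 1")
        if len(self.zipf_exponent) != len(self.group_names):
            raise ConfigError("zipf_exponent must align with group_names")
        if self.n_cells < 1 or self.n_samples_per_group < 1:
            raise ConfigError("n_cells and n_samples_per_group must be >= 1")
        for frac in (
            self.qc_fail_fraction,
            self.vdj_fraction,
            self.nonproductive_cell_fraction,
            self.db_exact_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("fractions must lie in [0, 1]")
        if self.marker_effect_size <= 0:
            raise ConfigError("marker_effect_size must be > 0")
        n_expanded = round(self.vdj_fraction * self.n_cells)
        if n_expanded < 1 and self.vdj_fraction > 0:
            raise ConfigError("vdj_fraction yields zero VDJ cells")


@dataclass
class GroundTruth:
    """Planted truth of a simulated cohort, keyed by sample name."""

    phenotype_of_cell: dict  # sample -> {barcode: phenotype}
    qc_fail: dict  # sample -> set of flagged barcodes
    spectrum: dict  # sample -> {clonotype_key: n_cells}
    db_distance: dict  # sample -> {clonotype_key: planted best distance}


@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    matrices: dict  # sample -> CountMatrix
    vdj: dict  # sample -> VdjTable
    antigen_db: AntigenDb
    truth: GroundTruth
    groups: dict  # sample -> group name
    config: SimConfig


def _random_strings(rng, alphabet, n, length) -> list:
    return [
        "".join(rng.choice(alphabet, size=length)) for _ in range(n)
    ]


def _unique_barcodes(rng, n) -> list:
    seen = set()
    out = []
    while len(out) < n:
        bc = "".join(rng.choice(NUCLEOTIDES, size=16)) + "-1"
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _nb_draw(rng, mean, size_param, shape):
    """Negative binomial with mean/size (dispersion) parameterization."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), shape)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=shape)


def _perturb_cdr3(rng, seq: str, n_edits: int) -> str:
    """Apply ``n_edits`` random substitutions at distinct positions."""
    chars = list(seq)
    positions = rng.choice(len(chars), size=min(n_edits, len(chars)), replace=False)
    for pos in positions:
        alternatives = [a for a in AMINO_ACIDS if a != chars[pos]]
        chars[pos] = str(rng.choice(alternatives))
    return "".join(chars)


def _simulate_expression(rng, config: SimConfig, phenotypes: np.ndarray):
    """Counts matrix plus gene annotation and QC-fail flags for one sample."""
    n = config.n_cells
    panel_genes = [g for panel in DEFAULT_PANELS.values() for g in panel]
    gene_symbols = (
        [f"HK{i+1}" for i in range(config.n_housekeeping_genes)]
        + [f"GENE{i+1}" for i in range(config.n_background_genes)]
        + panel_genes
        + [f"MT-SIM{i+1}" for i in range(config.n_mito_genes)]
    )
    gene_ids = [f"SIM{i:05d}" for i in range(len(gene_symbols))]

    hk = _nb_draw(
        rng,
        config.housekeeping_mean,
        config.housekeeping_nb_size,
        (config.n_housekeeping_genes, n),
    )
    bg = _nb_draw(
        rng,
        config.background_mean,
        config.background_nb_size,
        (config.n_background_genes, n),
    )
    pheno_of_gene = {
        g: pheno for pheno, genes in DEFAULT_PANELS.items() for g in genes
    }
    panel_rows = []
    for g in panel_genes:
        boost = np.where(
            phenotypes == pheno_of_gene[g], config.marker_effect_size, 1.0
        )
        panel_rows.append(
            _nb_draw(rng, config.panel_base_mean * boost, config.panel_nb_size, (n,))
        )
    panel = np.vstack(panel_rows)

    counts = np.vstack([hk, bg, panel]).astype(np.int64)

    # deliberately low-quality cells: first half of the flagged set loses
    # detected genes, second half gets a high mitochondrial fraction
    n_fail = round(config.qc_fail_fraction * n)
    fail_idx = rng.permutation(n)[:n_fail]
    gene_fail = set(fail_idx[: n_fail // 2].tolist())
    mito_fail = set(fail_idx[n_fail // 2 :].tolist())
    n_bg_keep = 250  # leaves < 500 detectable genes in gene-dropout cells
    bg_lo = config.n_housekeeping_genes
    for j in gene_fail:
        keep = rng.choice(config.n_background_genes, size=n_bg_keep, replace=False)
        mask = np.ones(counts.shape[0], dtype=bool)
        mask[bg_lo + keep] = False
        mask[bg_lo + config.n_background_genes :] = False  # keep panel genes
        counts[mask, j] = 0
        counts[: config.n_housekeeping_genes, j] = 0

    # mitochondrial counts from per-cell target fractions
    target_f = rng.beta(*config.mito_beta, size=n)
    mito = np.zeros((config.n_mito_genes, n), dtype=np.int64)
    totals = counts.sum(axis=0)
    for j in range(n):
        if j in mito_fail:
            f = rng.uniform(0.15, 0.3)
            m_total = int(np.ceil(f * totals[j] / (1 - f)))
        else:
            f = min(target_f[j], 0.09)
            m_total = int(np.floor(f * totals[j] / (1 - f)))
        if m_total > 0:
            mito[:, j] = rng.multinomial(
                m_total, np.full(config.n_mito_genes, 1 / config.n_mito_genes)
            )
    counts = np.vstack([counts, mito])

    if n_fail:
        detected = (counts > 0).sum(axis=0)
        tot = counts.sum(axis=0)
        mito_frac = mito.sum(axis=0) / np.maximum(tot, 1)
        for j in range(n):
            flagged = j in gene_fail or j in mito_fail
            fails = detected[j] < 500 or mito_frac[j] > 0.1
            if flagged != fails:
                raise ConfigError(
                    "infeasible config: planted QC flags do not honor the "
                    "default thresholds (cell "
                    f"{j}: detected={detected[j]}, mito={mito_frac[j]:.3f})"
                )
    return counts, gene_ids, gene_symbols, sorted(gene_fail | mito_fail)


def _zipf_assign(rng, n_cells_vdj: int, exponent: float) -> np.ndarray:
    """Assign each cell a clonotype pool index under a Zipf rank law."""
    pool = max(1, n_cells_vdj)
    ranks = np.arange(1, pool + 1, dtype=float)
    probs = ranks ** (-exponent)
    probs /= probs.sum()
    return rng.choice(pool, size=n_cells_vdj, p=probs)


def _simulate_vdj(rng, config: SimConfig, barcodes, exponent: float):
    """VdjTable plus planted clonotype spectrum for one sample."""
    n_vdj = round(config.vdj_fraction * len(barcodes))
    vdj_cells = [barcodes[i] for i in rng.permutation(len(barcodes))[:n_vdj]]
    n_orphan = round(config.nonproductive_cell_fraction * n_vdj)
    orphans = vdj_cells[:n_orphan]
    productive_cells = vdj_cells[n_orphan:]

    assignment = _zipf_assign(rng, len(productive_cells), exponent)
    pool_size = int(assignment.max()) + 1 if len(assignment) else 0
    pairs = {}
    used = set()
    for i in range(pool_size):
        while True:
            la = int(rng.integers(8, 17))
            lb = int(rng.integers(8, 17))
            cdr3a = "CA" + "".join(rng.choice(AMINO_ACIDS, size=la - 2))
            cdr3b = "CASS" + "".join(rng.choice(AMINO_ACIDS, size=lb - 4))
            if (cdr3a, cdr3b) not in used:
                used.add((cdr3a, cdr3b))
                pairs[i] = (cdr3a, cdr3b)
                break

    rows = []
    spectrum = {}

    def _contig(barcode, chain, cdr3, productive, clonotype_id):
        length = len(cdr3)
        umis = int(rng.integers(1, 6))
        return {
            "barcode": barcode,
            "is_cell": True,
            "high_confidence": True,
            "chain": chain,
            "v_gene": f"{chain}V{int(rng.integers(1, 31))}",
            "d_gene": f"TRBD{int(rng.integers(1, 3))}" if chain == "TRB" else "",
            "j_gene": f"{chain}J{int(rng.integers(1, 31))}",
            "cdr3_aa": cdr3,
            "cdr3_nt": "".join(rng.choice(NUCLEOTIDES, size=3 * length)),
            "reads": umis * int(rng.integers(20, 60)),
            "umis": umis,
            "productive": productive,
            "raw_clonotype_id": clonotype_id,
        }

    for barcode, pool_idx in zip(productive_cells, assignment):
        cdr3a, cdr3b = pairs[int(pool_idx)]
        cid = f"clonotype{int(pool_idx) + 1}"
        rows.append(_contig(barcode, "TRA", cdr3a, True, cid))
        rows.append(_contig(barcode, "TRB", cdr3b, True, cid))
        key = ";".join(sorted([f"TRA:{cdr3a}", f"TRB:{cdr3b}"]))
        spectrum[key] = spectrum.get(key, 0) + 1
    for barcode in orphans:
        lb = int(rng.integers(8, 17))
        cdr3b = "CASS" + "".join(rng.choice(AMINO_ACIDS, size=lb - 4))
        rows.append(_contig(barcode, "TRB", cdr3b, False, ""))

    df = pd.DataFrame(rows, columns=VDJ_COLUMNS)
    return VdjTable(df), spectrum


def _build_antigen_db(rng, config: SimConfig, spectra: dict):
    """DB with planted exact/perturbed entries for top clonotypes + decoys."""
    from tilscope.antigen import levenshtein  # local import avoids a cycle

    antigens = [
        ("MART-1", "ELAGIGILTV", "Melanoma", "Cancer"),
        ("NS4B", "LLWNGPMAV", "Yellow fever", "Pathogens"),
        ("pp65", "NLVPMVATV", "CMV", "Pathogens"),
        ("BMLF1", "GLCTLVAML", "EBV", "Pathogens"),
        ("NY-ESO-1", "SLLMWITQC", "Carcinoma", "Cancer"),
        ("M1", "GILGFVFTL", "Influenza", "Pathogens"),
    ]
    records = []
    db_distance = {}
    for sample, spectrum in spectra.items():
        ordered = sorted(spectrum, key=lambda k: (-spectrum[k], k))[:10]
        db_distance[sample] = {}
        for key in ordered:
            chains = dict(tok.split(":", 1) for tok in key.split(";"))
            beta = chains.get("TRB", "")
            alpha = chains.get("TRA", "")
            if not beta:
                continue
            antigen = antigens[int(rng.integers(len(antigens)))]
            if rng.random() < config.db_exact_fraction:
                db_beta, db_alpha = beta, alpha
            else:
                # both chains perturbed at the same depth so the planted
                # distance holds under any chain policy
                d = int(rng.choice(config.planted_distances))
                db_beta = _perturb_cdr3(rng, beta, d)
                db_alpha = _perturb_cdr3(rng, alpha, d) if alpha else ""
            if rng.random() >= 0.5:
                db_alpha = ""
            planted = levenshtein(beta, db_beta)
            if db_alpha:
                planted = min(planted, levenshtein(alpha, db_alpha))
            records.append(
                {
                    "cdr3_alpha_aa": db_alpha,
                    "cdr3_beta_aa": db_beta,
                    "antigen_protein": antigen[0],
                    "epitope_peptide": antigen[1],
                    "pathology": antigen[2],
                    "category": antigen[3],
                }
            )
            prev = db_distance[sample].get(key)
            db_distance[sample][key] = (
                planted if prev is None else min(prev, planted)
            )
    for _ in range(config.n_db_decoys):
        lb = int(rng.integers(10, 18))
        antigen = antigens[int(rng.integers(len(antigens)))]
        records.append(
            {
                "cdr3_alpha_aa": "",
                "cdr3_beta_aa": "CASS" + "".join(rng.choice(AMINO_ACIDS, size=lb - 4)),
                "antigen_protein": antigen[0],
                "epitope_peptide": antigen[1],
                "pathology": antigen[2],
                "category": antigen[3],
            }
        )
    df = pd.DataFrame(records, columns=ANTIGEN_COLUMNS)
    return AntigenDb(df=df), db_distance


def simulate_dataset(config: SimConfig | None = None) -> SimulatedDataset:
    """Generate a full synthetic cohort under ``config``.

    Returns per-sample CountMatrix and VdjTable objects, a shared AntigenDb,
    and the planted :class:`GroundTruth`.  The same config and seed always
    produce identical output.
    """
    config = config or SimConfig()
    phenotype_names = list(PHENOTYPE_PRIORITY)
    root = np.random.SeedSequence(config.seed)
    n_samples = len(config.group_names) * config.n_samples_per_group
    streams = root.spawn(n_samples + 1)

    matrices, vdj_tables, groups = {}, {}, {}
    truth = GroundTruth({}, {}, {}, {})
    spectra = {}
    idx = 0
    for group, exponent in zip(config.group_names, config.zipf_exponent):
        for rep in range(config.n_samples_per_group):
            sample = f"{group}{rep + 1}"
            rng = np.random.default_rng(streams[idx])
            idx += 1
            phenotypes = rng.choice(
                phenotype_names, size=config.n_cells, p=config.phenotype_proportions
            )
            counts, gene_ids, gene_symbols, fail_cols = _simulate_expression(
                rng, config, phenotypes
            )
            barcodes = _unique_barcodes(rng, config.n_cells)
            matrices[sample] = CountMatrix(
                gene_ids=gene_ids,
                gene_symbols=gene_symbols,
                barcodes=barcodes,
                counts=sp.csr_matrix(counts),
            )
            vdj_tables[sample], spectrum = _simulate_vdj(
                rng, config, barcodes, exponent
            )
            groups[sample] = group
            spectra[sample] = spectrum
            truth.phenotype_of_cell[sample] = dict(zip(barcodes, phenotypes))
            truth.qc_fail[sample] = {barcodes[j] for j in fail_cols}
            truth.spectrum[sample] = spectrum

    db_rng = np.random.default_rng(streams[-1])
    antigen_db, truth.db_distance = _build_antigen_db(db_rng, config, spectra)
    logger.info(
        "simulated %d samples x %d cells, %d antigen DB rows",
        n_samples,
        config.n_cells,
        len(antigen_db),
    )
    return SimulatedDataset(
        matrices=matrices,
        vdj=vdj_tables,
        antigen_db=antigen_db,
        truth=truth,
        groups=groups,
        config=config,
    )


#: Named configurations behind :func:`fixture_suite`.
FIXTURE_CONFIGS = {
    # no structure at all: marker effect 1, flat mixture
    "null": SimConfig(
        n_cells=200,
        n_samples_per_group=1,
        group_names=("NULL",),
        zipf_exponent=(1.0,),
        marker_effect_size=1.0,
        seed=101,
    ),
    # 4 planted phenotype clusters, 400 cells, clean QC
    "four_phenotypes": SimConfig(
        n_cells=400,
        n_samples_per_group=1,
        group_names=("S",),
        zipf_exponent=(1.0,),
        seed=202,
    ),
    # strongly expanded repertoire (immunocompetent-like)
    "expanded_repertoire": SimConfig(
        n_cells=400,
        n_samples_per_group=1,
        group_names=("SCC",),
        zipf_exponent=(1.5,),
        seed=303,
    ),
    # flat repertoire (transplant-like)
    "flat_repertoire": SimConfig(
        n_cells=400,
        n_samples_per_group=1,
        group_names=("TSCC",),
        zipf_exponent=(0.2,),
        seed=303,
    ),
    # 20% deliberately low-quality cells
    "qc_mixed": SimConfig(
        n_cells=300,
        n_samples_per_group=1,
        group_names=("S",),
        zipf_exponent=(1.0,),
        qc_fail_fraction=0.2,
        seed=404,
    ),
}


def fixture_suite(names=None) -> dict:
    """Deterministic catalog of small named datasets used across tests.

    Parameters
    ----------
    names : iterable of str, optional
        Subset of fixture names to generate (all by default).
    """
    wanted = list(names) if names is not None else list(FIXTURE_CONFIGS)
    unknown = [n for n in wanted if n not in FIXTURE_CONFIGS]
    if unknown:
        raise ConfigError(f"unknown fixtures: {unknown}")
    return {name: simulate_dataset(FIXTURE_CONFIGS[name]) for name in wanted}
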