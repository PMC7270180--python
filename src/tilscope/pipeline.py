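"""End-to-end orchestration: configuration, per-sample stages, cohort report.

``run_pipeline`` composes the library stages for every sample — QC,
ranked-GLSF normalization, two-round PCA, silhouette-selected k-means,
marker detection, phenotype assignment, clonotype statistics and antigen
matching — then adds cohort-level group comparisons.  All stage parameters
are echoed into the report bundle for provenance, and all non-plot outputs
are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tilscope import antigen as antigen_mod
from tilscope import clonotype as clono_mod
from tilscope import phenotype as pheno_mod
from tilscope.cluster import (
    ClusterConfig,
    GeneModelConfig,
    PcaRefineConfig,
    cluster_kmeans_silhouette,
    two_round_pca,
)
from tilscope.errors import ConfigError
from tilscope.qc import (
    NormalizationConfig,
    QcThresholds,
    compute_cell_qc,
    compute_gene_stats,
    filter_cells,
    ranked_glsf_normalize,
)
from tilscope.tenx_io import (
    harmonize_barcodes,
    read_antigen_db,
    read_contig_annotations,
    read_expression_triplet,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Full pipeline configuration.

    samples : dict sample -> {"expression": triplet dir, "contigs": CSV path}
        (the "contigs" entry may be absent for expression-only samples).
    groups : dict sample -> group name.
    antigen_db : path to the antigen CSV, or None to skip matching.
    seed : mandatory; drives k-means restarts (and any optional embedding).
    """

    samples: dict
    groups: dict
    seed: int
    antigen_db: str | None = None
    outdir: str | None = None
    qc: QcThresholds = field(default_factory=QcThresholds)
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    gene_model: GeneModelConfig = field(default_factory=GeneModelConfig)
    refine: PcaRefineConfig = field(default_factory=PcaRefineConfig)
    clustering: ClusterConfig = field(default_factory=ClusterConfig)
    panels: pheno_mod.PhenotypePanels = field(default_factory=pheno_mod.PhenotypePanels)
    antigen: antigen_mod.AntigenCallConfig = field(
        default_factory=antigen_mod.AntigenCallConfig
    )
    clonotype_mode: str = "cdr3_pair"
    top_n_clonotypes: int = 10

    def validate(self) -> None:
        if not self.samples:
            raise ConfigError("no samples configured")
        for name, paths in self.samples.items():
            if name not in self.groups:
                raise ConfigError(f"sample {name!r} has no group assignment")
            expr = paths.get("expression")
            if expr is None or not Path(expr).exists():
                raise ConfigError(f"sample {name!r}: expression path missing: {expr}")
            contigs = paths.get("contigs")
            if contigs is not None and not Path(contigs).exists():
                raise ConfigError(f"sample {name!r}: contigs path missing: {contigs}")
        if self.antigen_db is not None and not Path(self.antigen_db).exists():
            raise ConfigError(f"antigen DB path missing: {self.antigen_db}")


def _params_echo(config: PipelineConfig) -> dict:
    def _plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): _plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return obj

    echo = {
        f.name: _plain(getattr(config, f.name))
        for f in dataclasses.fields(config)
        if f.name not in ("samples",)
    }
    echo["samples"] = {
        name: {k: str(v) for k, v in paths.items()}
        for name, paths in config.samples.items()
    }
    return echo


def _run_sample(name: str, paths: dict, config: PipelineConfig) -> dict:
    logger.info("sample %s: expression stage", name)
    matrix = read_expression_triplet(paths["expression"])
    qc_stats = compute_cell_qc(matrix, config.qc)
    filtered = filter_cells(matrix, qc_stats, config.qc)
    normalized, size_factors = ranked_glsf_normalize(filtered, config.normalization)
    gene_names = filtered.gene_symbols
    gene_stats = compute_gene_stats(normalized, gene_names)
    clustering = dataclasses.replace(config.clustering, seed=config.seed)
    embedding = two_round_pca(
        normalized,
        gene_stats,
        config.gene_model,
        config.refine,
        n_pcs=clustering.n_pcs,
        barcodes=filtered.barcodes,
    )
    assignment = cluster_kmeans_silhouette(embedding, clustering)
    markers = pheno_mod.marker_test(normalized, gene_names, assignment.labels)
    phenotypes = pheno_mod.score_phenotypes(
        normalized,
        gene_names,
        assignment.labels,
        config.panels,
        barcodes=filtered.barcodes,
    )
    result = {
        "matrix": filtered,
        "qc": qc_stats,
        "size_factors": size_factors,
        "embedding": embedding,
        "clusters": assignment,
        "markers": markers,
        "phenotypes": phenotypes,
    }

    contigs = paths.get("contigs")
    if contigs is None:
        logger.info("sample %s: no VDJ library; clonotype stage skipped", name)
        return result
    logger.info("sample %s: VDJ stage", name)
    vdj = read_contig_annotations(contigs)
    mapping = harmonize_barcodes(filtered, vdj)
    summary = clono_mod.build_clonotypes(vdj, mode=config.clonotype_mode)
    result.update(
        {
            "vdj": vdj,
            "barcode_map": mapping,
            "clonotypes": summary,
            "clonality": clono_mod.clonality_report(summary),
            "partition": clono_mod.frequency_partition(summary),
            "clonotype_phenotypes": clono_mod.link_clonotypes_to_phenotypes(
                summary, phenotypes, mapping, top_n=config.top_n_clonotypes
            ),
        }
    )
    return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for every sample, then cohort-level comparisons.

    Returns the report bundle: ``{"samples": {...}, "cohort": {...},
    "parameters": {...}}``.  When ``config.outdir`` is set, CSV/JSON outputs
    are also written there (one subdirectory per sample).
    """
    config.validate()
    bundle = {"samples": {}, "cohort": {}, "parameters": _params_echo(config)}

    db = read_antigen_db(config.antigen_db) if config.antigen_db else None
    for name in sorted(config.samples):
        result = _run_sample(name, config.samples[name], config)
        if db is not None and "clonotypes" in result:
            matches = antigen_mod.match_clonotypes(
                result["clonotypes"], db, config.antigen, config.top_n_clonotypes
            )
            queries = list(
                result["clonotypes"]
                .table.nsmallest(config.top_n_clonotypes, "rank")["key"]
            )
            status, fractions = antigen_mod.classify_antigen_status(
                matches, queries, config.antigen
            )
            result["antigen_matches"] = matches
            result["antigen_status"] = status
            result["antigen_fractions"] = fractions
        bundle["samples"][name] = result

    bundle["cohort"] = _cohort_stats(bundle["samples"], config)
    if config.outdir:
        _write_bundle(bundle, Path(config.outdir))
    return bundle


def _cohort_stats(samples: dict, config: PipelineConfig) -> dict:
    sample_of_cell = {}
    assignments = []
    for name, result in samples.items():
        pheno = result["phenotypes"]
        for barcode in pheno.barcodes:
            sample_of_cell[barcode] = name
        assignments.append(pheno)
    merged = pheno_mod.PhenotypeAssignment(
        cluster_labels={},
        cluster_scores=pd.DataFrame(),
        cell_labels=np.concatenate([a.cell_labels for a in assignments]),
        barcodes=[b for a in assignments for b in a.barcodes],
    )
    per_sample, per_group = pheno_mod.phenotype_proportions(
        merged, sample_of_cell, group_of_sample=config.groups
    )
    cohort = {"proportions_per_sample": per_sample, "proportions_per_group": per_group}

    group_names = sorted(set(config.groups[s] for s in samples))
    if len(group_names) == 2:
        ga, gb = group_names
        members = {
            g: [s for s in samples if config.groups[s] == g] for g in group_names
        }
        label_df = pd.DataFrame(
            {
                "group": [
                    config.groups[sample_of_cell[b]] for b in merged.barcodes
                ],
                "phenotype": merged.cell_labels,
            }
        )
        comparisons = {}
        for pheno in per_sample.columns:
            counts = {
                g: (
                    int(
                        (
                            (label_df["group"] == g)
                            & (label_df["phenotype"] == pheno)
                        ).sum()
                    ),
                    int((label_df["group"] == g).sum()),
                )
                for g in group_names
            }
            comparisons[pheno] = pheno_mod.compare_proportions(
                counts[ga],
                counts[gb],
                per_sample.loc[members[ga], pheno].to_list(),
                per_sample.loc[members[gb], pheno].to_list(),
            )
        cohort["proportion_tests"] = comparisons

        richness = {
            g: [
                samples[s]["clonotypes"].n_clonotypes
                for s in members[g]
                if "clonotypes" in samples[s]
            ]
            for g in group_names
        }
        if richness[ga] and richness[gb]:
            cohort["richness"] = clono_mod.compare_clonotype_richness(
                richness[ga], richness[gb]
            )
    else:
        logger.info("cohort has %d group(s); group tests not computable", len(group_names))
        cohort["proportion_tests"] = None
        cohort["richness"] = None
    return cohort


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, set):
        return sorted(_jsonable(v) for v in obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"parameters": bundle["parameters"], "samples": {}, "cohort": {}}
    for name, result in bundle["samples"].items():
        sdir = outdir / name
        sdir.mkdir(exist_ok=True)
        result["qc"].to_csv(sdir / "qc.csv")
        result["size_factors"].to_csv(sdir / "size_factors.csv")
        emb = result["embedding"]
        pd.DataFrame(
            emb.coordinates,
            index=pd.Index(emb.barcodes, name="barcode"),
            columns=[f"PC{i+1}" for i in range(emb.n_dims)],
        ).to_csv(sdir / "embedding.csv")
        clusters = result["clusters"]
        pd.DataFrame(
            {
                "cluster": clusters.labels,
                "phenotype": result["phenotypes"].cell_labels,
            },
            index=pd.Index(result["phenotypes"].barcodes, name="barcode"),
        ).to_csv(sdir / "clusters.csv")
        result["markers"].to_csv(sdir / "markers.csv", index=False)
        sample_report = {
            "k": clusters.k,
            "mean_silhouette": clusters.mean_silhouette,
        }
        if "clonality" in result:
            result["partition"].to_csv(sdir / "clonality_partition.csv", index=False)
            result["clonotypes"].table.to_csv(sdir / "clonotypes.csv", index=False)
            result["clonotype_phenotypes"].to_csv(
                sdir / "clonotype_phenotypes.csv", index=False
            )
            sample_report["clonality"] = _jsonable(result["clonality"])
        if "antigen_matches" in result:
            result["antigen_matches"].hits.to_csv(
                sdir / "antigen_matches.csv", index=False
            )
            result["antigen_status"].to_csv(sdir / "antigen_status.csv", index=False)
            sample_report["antigen_fractions"] = _jsonable(
                result["antigen_fractions"]
            )
        report["samples"][name] = sample_report

    cohort = bundle["cohort"]
    cohort["proportions_per_sample"].to_csv(outdir / "proportions_per_sample.csv")
    if cohort.get("proportions_per_group") is not None:
        cohort["proportions_per_group"].to_csv(outdir / "proportions_per_group.csv")
    report["cohort"] = {
        "proportion_tests": _jsonable(cohort.get("proportion_tests")),
        "richness": _jsonable(cohort.get("richness")),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("report bundle written to %s", outdir)


def render_figures(bundle: dict, outdir) -> list:
    """Render the standard figures for a report bundle.

    Produces, per sample: a clonality bar chart of the repertoire partition
    (skipped with a log note when the sample lacks VDJ data) and a 2-D
    scatter of the first two principal components colored by cluster.
    Plotting failures are logged, never fatal, and cannot corrupt data
    outputs.  Returns the list of files written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, result in bundle["samples"].items():
        try:
            if "partition" in result:
                part = result["partition"]
                fig, ax = plt.subplots(figsize=(6, 4))
                ax.bar(part["category"], part["percent"], color="#4878a8")
                ax.set_ylabel("% of cells")
                ax.set_title(f"{name}: repertoire partition")
                ax.tick_params(axis="x", rotation=75)
                fig.tight_layout()
                path = outdir / f"{name}_clonality.png"
                fig.savefig(path, dpi=120)
                plt.close(fig)
                written.append(path)
            else:
                logger.info("sample %s: no VDJ data; clonality plot skipped", name)

            emb = result["embedding"]
            labels = result["clusters"].labels
            fig, ax = plt.subplots(figsize=(5, 5))
            for lab in sorted(set(labels)):
                mask = labels == lab
                ax.scatter(
                    emb.coordinates[mask, 0],
                    emb.coordinates[mask, 1],
                    s=8,
                    label=f"cluster {lab}",
                )
            ax.set_xlabel("PC1")
            ax.set_ylabel("PC2")
            ax.legend(markerscale=2, fontsize=8)
            ax.set_title(name)
            fig.tight_layout()
            path = outdir / f"{name}_embedding.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
        except Exception:  # plotting must never corrupt data outputs
            logger.exception("figure rendering failed for sample %s", name)
    return written
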