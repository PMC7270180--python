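"""Gene-model selection, two-round PCA, and silhouette-selected k-means.

The gene model keeps genes that are both highly covered (top ``top_coverage``
genes by number of expressing cells) and highly variable (Fano dispersion
strictly above ``min_dispersion``).  A first PCA on those genes is refined by
re-running PCA on the genes with the largest and smallest loadings in each of
the first ten components; clustering then runs k-means (euclidean) on the top
principal components, selecting k by mean silhouette width over a scanned
range.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from tilscope.errors import ConfigError, EmptyGeneModelError, NoClusterStructureError

logger = logging.getLogger(__name__)


@dataclass
class GeneModelConfig:
    """Coverage/dispersion gene selection.

    top_coverage : size of the high-coverage set (default 500).
    min_dispersion : strict Fano-factor threshold (default 1.5).
    mode : "intersection" (default) keeps genes passing both criteria;
        "union" keeps genes passing either.
    """

    top_coverage: int = 500
    min_dispersion: float = 1.5
    mode: str = "intersection"

    def __post_init__(self):
        if self.top_coverage < 1:
            raise ConfigError("top_coverage must be >= 1")
        if self.min_dispersion < 0:
            raise ConfigError("min_dispersion must be >= 0")
        if self.mode not in ("intersection", "union"):
            raise ConfigError(f"unknown gene-model mode {self.mode!r}")


@dataclass
class PcaRefineConfig:
    """Loading-based gene refinement after the first PCA round.

    For each of the first ``n_dims_scan`` components take the ``top_k`` genes
    with the largest (signed) loadings and the ``bottom_k`` with the most
    negative loadings.
    """

    n_dims_scan: int = 10
    top_k: int = 20
    bottom_k: int = 20

    def __post_init__(self):
        if min(self.n_dims_scan, self.top_k, self.bottom_k) < 1:
            raise ConfigError("all PcaRefineConfig fields must be >= 1")


@dataclass
class ClusterConfig:
    """k-means model-selection parameters (euclidean distance throughout)."""

    n_pcs: int = 10
    k_min: int = 2
    k_max: int = 10
    seed: int = 0
    n_init: int = 10

    def __post_init__(self):
        if not 2 <= self.k_min <= self.k_max:
            raise ConfigError("need 2 <= k_min <= k_max")


@dataclass
class Embedding:
    """PCA result.

    coordinates : cells x dims scores.
    component_sdev : per-component standard deviation, non-increasing.
    loadings : genes x dims loading matrix for the genes in ``genes``.
    """

    coordinates: np.ndarray
    component_sdev: np.ndarray
    loadings: np.ndarray
    genes: list
    barcodes: list | None = None

    @property
    def n_dims(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class ClusterAssignment:
    """k-means result with the silhouette model-selection scan.

    labels : per-cell cluster ids in 1..k.
    silhouette_by_k : DataFrame indexed by scanned k with column
        ``mean_silhouette``.
    """

    labels: np.ndarray
    k: int
    mean_silhouette: float
    silhouette_by_k: pd.DataFrame
    barcodes: list | None = None


def select_model_genes(stats: pd.DataFrame, config: GeneModelConfig | None = None):
    """Select the gene model from per-gene statistics.

    ``stats`` is the frame from :func:`tilscope.qc.compute_gene_stats`
    (indexed by gene, columns ``coverage`` and ``dispersion``), computed on
    the normalized matrix.  Returns gene names ordered by descending
    coverage (ties by input order).

    Raises
    ------
    EmptyGeneModelError
        When no gene passes; relax ``min_dispersion`` or ``top_coverage``.
    """
    config = config or GeneModelConfig()
    coverage = stats["coverage"].to_numpy()
    dispersion = stats["dispersion"].to_numpy()
    order = np.argsort(-coverage, kind="stable")
    top_set = np.zeros(len(stats), dtype=bool)
    top_set[order[: config.top_coverage]] = True
    disp_set = dispersion > config.min_dispersion
    chosen = (top_set | disp_set) if config.mode == "union" else (top_set & disp_set)
    if not chosen.any():
        raise EmptyGeneModelError(
            "no gene passes coverage+dispersion selection; relax "
            f"min_dispersion (={config.min_dispersion}) or raise top_coverage"
        )
    selected = [i for i in order if chosen[i]]
    return [stats.index[i] for i in selected]


def pca(
    matrix: np.ndarray,
    genes,
    n_components: int,
    barcodes=None,
) -> Embedding:
    """Principal component analysis of a genes x cells matrix.

    Genes are centered before the decomposition.  The result is
    sign-stabilized: within each component the largest-magnitude loading is
    forced positive, so repeated runs (and tests) are deterministic.
    ``n_components`` beyond the matrix rank is truncated with a warning.
    """
    X = np.asarray(matrix, dtype=float).T  # cells x genes
    n_cells, n_genes = X.shape
    if n_cells < 2:
        raise ValueError("PCA needs at least 2 cells")
    max_rank = min(n_cells, n_genes)
    if n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds max rank {max_rank}; truncating",
            stacklevel=2,
        )
        n_components = max_rank
    model = PCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(X)
    loadings = model.components_.T.copy()  # genes x dims
    sdev = np.sqrt(model.explained_variance_.copy())
    # sign stabilization
    for j in range(loadings.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, j]))
        if loadings[pivot, j] < 0:
            loadings[:, j] *= -1
            coords[:, j] *= -1
    return Embedding(
        coordinates=coords,
        component_sdev=sdev,
        loadings=loadings,
        genes=list(genes),
        barcodes=list(barcodes) if barcodes is not None else None,
    )


def refine_gene_model(
    embedding: Embedding, config: PcaRefineConfig | None = None
):
    """Genes with extreme loadings in the leading components.

    For each of the first ``n_dims_scan`` dimensions, take the ``top_k``
    genes with the largest loadings and the ``bottom_k`` with the smallest
    (most negative).  The union is de-duplicated in first-appearance order
    (dim 1 top, dim 1 bottom, dim 2 top, ...).
    """
    config = config or PcaRefineConfig()
    n_dims = embedding.loadings.shape[1]
    if n_dims < config.n_dims_scan:
        warnings.warn(
            f"embedding has {n_dims} dims < n_dims_scan={config.n_dims_scan}; "
            "using what exists",
            stacklevel=2,
        )
    seen = {}
    for dim in range(min(config.n_dims_scan, n_dims)):
        load = embedding.loadings[:, dim]
        order = np.argsort(-load, kind="stable")
        for i in order[: config.top_k]:
            seen.setdefault(embedding.genes[i], None)
        for i in order[::-1][: config.bottom_k]:
            seen.setdefault(embedding.genes[i], None)
    return list(seen)


def two_round_pca(
    norm_matrix: np.ndarray,
    gene_stats: pd.DataFrame,
    gm_config: GeneModelConfig | None = None,
    refine_config: PcaRefineConfig | None = None,
    n_pcs: int = 10,
    barcodes=None,
) -> Embedding:
    """Gene model -> PCA -> loading-based refinement -> PCA.

    ``norm_matrix`` is the normalized genes x cells matrix aligned with
    ``gene_stats``'s index.  The second-round embedding is re-centered on
    the refined gene set and truncated to ``n_pcs`` components.
    """
    gm_config = gm_config or GeneModelConfig()
    refine_config = refine_config or PcaRefineConfig()
    norm_matrix = np.asarray(norm_matrix, dtype=float)
    gene_index = {g: i for i, g in enumerate(gene_stats.index)}

    genes1 = select_model_genes(gene_stats, gm_config)
    rows1 = [gene_index[g] for g in genes1]
    n1 = min(
        max(n_pcs, refine_config.n_dims_scan), len(genes1), norm_matrix.shape[1]
    )
    emb1 = pca(norm_matrix[rows1, :], genes1, n1, barcodes=barcodes)

    genes2 = refine_gene_model(emb1, refine_config)
    rows2 = [gene_index[g] for g in genes2]
    n2 = min(n_pcs, len(genes2), norm_matrix.shape[1])
    emb2 = pca(norm_matrix[rows2, :], genes2, n2, barcodes=barcodes)
    logger.info(
        "two-round PCA: %d model genes -> %d refined genes, %d PCs",
        len(genes1),
        len(genes2),
        emb2.n_dims,
    )
    return emb2


def cluster_kmeans_silhouette(
    embedding: Embedding, config: ClusterConfig | None = None
) -> ClusterAssignment:
    """k-means over a scanned k range, selecting k by mean silhouette width.

    For each k in [k_min, k_max] runs k-means (euclidean, ``n_init``
    restarts, fixed seed) on the first ``n_pcs`` coordinates and computes the
    mean silhouette width; the k maximizing it wins, ties going to the
    smaller k (parsimony).  Cluster ids are renumbered 1..k by order of first
    appearance so the labeling is deterministic.

    Raises
    ------
    NoClusterStructureError
        If all embedded points are identical.
    """
    config = config or ClusterConfig()
    X = embedding.coordinates[:, : config.n_pcs]
    n_cells = X.shape[0]
    if np.allclose(X, X[0]):
        raise NoClusterStructureError("all cells identical in the embedding")
    k_max = min(config.k_max, n_cells - 1)
    if config.k_min > k_max:
        raise ConfigError(f"k_min={config.k_min} exceeds usable k_max={k_max}")

    scan = {}
    labels_by_k = {}
    for k in range(config.k_min, k_max + 1):
        km = KMeans(
            n_clusters=k,
            n_init=config.n_init,
            random_state=config.seed,
        ).fit(X)
        labels = km.labels_
        if len(np.unique(labels)) < 2:
            score = -1.0
        else:
            score = float(silhouette_score(X, labels, metric="euclidean"))
        scan[k] = score
        labels_by_k[k] = labels

    best_k = max(scan, key=lambda k: (scan[k], -k))
    raw = labels_by_k[best_k]
    # renumber 1..k by first appearance
    remap = {}
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    labels = np.array([remap[lab] for lab in raw], dtype=int)
    table = pd.DataFrame(
        {"mean_silhouette": [scan[k] for k in sorted(scan)]},
        index=pd.Index(sorted(scan), name="k"),
    )
    logger.info("silhouette scan selected k=%d (score %.4f)", best_k, scan[best_k])
    return ClusterAssignment(
        labels=labels,
        k=best_k,
        mean_silhouette=scan[best_k],
        silhouette_by_k=table,
        barcodes=embedding.barcodes,
    )


def embed_2d(embedding: Embedding, method: str = "umap", seed: int = 0) -> np.ndarray:
    """Project an embedding to 2-D for visualization.

    Thin delegation contract over UMAP or t-SNE: output is cells x 2, finite,
    and identical across calls with the same seed.  Algorithm internals are
    deliberately out of scope.
    """
    X = embedding.coordinates
    n = X.shape[0]
    if method == "umap":
        import umap  # deferred: numba compilation is slow at import

        reducer = umap.UMAP(
            n_components=2,
            random_state=seed,
            n_neighbors=max(2, min(15, n - 1)),
        )
        coords = reducer.fit_transform(X)
    elif method == "tsne":
        from sklearn.manifold import TSNE

        coords = TSNE(
            n_components=2,
            random_state=seed,
            perplexity=min(30.0, max(1.0, (n - 1) / 3.0)),
            init="pca" if X.shape[1] >= 2 else "random",
        ).fit_transform(X)
    else:
        raise ConfigError(f"unknown 2-D embedding method {method!r}")
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("2-D embedding produced non-finite coordinates")
    return coords
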