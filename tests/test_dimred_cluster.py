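import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from oracles import silhouette_by_loops
from tilscope.cluster import (
    ClusterConfig,
    Embedding,
    GeneModelConfig,
    PcaRefineConfig,
    cluster_kmeans_silhouette,
    embed_2d,
    pca,
    refine_gene_model,
    select_model_genes,
    two_round_pca,
)
from tilscope.errors import ConfigError, EmptyGeneModelError, NoClusterStructureError


def stats_frame(coverage, dispersion):
    return pd.DataFrame(
        {"base_mean": 1.0, "coverage": coverage, "dispersion": dispersion},
        index=pd.Index([f"G{i}" for i in range(len(coverage))], name="gene"),
    )


class TestGeneModel:
    def test_intersection_of_coverage_and_dispersion(self):
        stats = stats_frame([10, 9, 8, 7], [2, 2, 1, 2])
        genes = select_model_genes(stats, GeneModelConfig(top_coverage=3))
        # G2 fails dispersion, G3 falls outside the top-3 coverage set
        assert genes == ["G0", "G1"]

    def test_relaxed_thresholds_keep_all_expressed_genes(self):
        stats = stats_frame([5, 4, 3], [1.0, 0.5, 2.0])
        genes = select_model_genes(
            stats, GeneModelConfig(top_coverage=10, min_dispersion=0)
        )
        assert genes == ["G0", "G1", "G2"]

    def test_union_mode(self):
        stats = stats_frame([10, 9, 8], [0.1, 0.1, 9.0])
        genes = select_model_genes(
            stats, GeneModelConfig(top_coverage=1, min_dispersion=1.5, mode="union")
        )
        assert set(genes) == {"G0", "G2"}

    def test_empty_selection_raises(self):
        stats = stats_frame([10, 9], [1.0, 1.5])
        with pytest.raises(EmptyGeneModelError):
            select_model_genes(stats)


class TestPca:
    def test_known_covariance_principal_axis(self):
        # four symmetric points realize covariance [[2,1],[1,2]] exactly:
        # (+-sqrt3, +-sqrt3) and (1,-1),(-1,1); leading eigenvector (1,1)/sqrt2
        a = np.sqrt(3.0)
        cells = np.array([[a, a], [-a, -a], [1.0, -1.0], [-1.0, 1.0]])
        emb = pca(cells.T, ["G0", "G1"], n_components=2)
        axis = emb.loadings[:, 0]
        assert np.abs(axis) == pytest.approx([1 / np.sqrt(2)] * 2)
        assert emb.component_sdev[0] > emb.component_sdev[1]

    def test_collinear_cells_have_rank_one(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        cells = np.outer(t, [1.0, 2.0, -1.0])  # on a line in gene space
        emb = pca(cells.T, ["a", "b", "c"], n_components=3)
        assert emb.component_sdev[0] > 0
        assert emb.component_sdev[1:] == pytest.approx([0.0, 0.0], abs=1e-9)

    def test_identical_cells_give_zero_embedding(self):
        cells = np.ones((5, 3))
        emb = pca(cells.T, ["a", "b", "c"], n_components=2)
        assert emb.coordinates == pytest.approx(np.zeros((5, 2)), abs=1e-12)
        assert emb.component_sdev == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_sign_stabilization_makes_repeat_runs_identical(self, rng):
        X = rng.normal(size=(6, 30))
        emb1 = pca(X, list("abcdef"), 3)
        emb2 = pca(X.copy(), list("abcdef"), 3)
        assert emb1.coordinates == pytest.approx(emb2.coordinates)
        for j in range(3):
            pivot = np.argmax(np.abs(emb1.loadings[:, j]))
            assert emb1.loadings[pivot, j] > 0

    def test_variance_conservation(self, rng):
        X = rng.normal(size=(8, 20))
        emb = pca(X, [f"g{i}" for i in range(8)], n_components=8)
        total_in = np.var(X.T - X.T.mean(axis=0), axis=0, ddof=1).sum()
        total_out = np.var(emb.coordinates, axis=0, ddof=1).sum()
        assert total_out == pytest.approx(total_in, rel=1e-8)

    def test_excess_components_truncated_with_warning(self, rng):
        X = rng.normal(size=(3, 5))
        with pytest.warns(UserWarning, match="truncating"):
            emb = pca(X, list("abc"), n_components=10)
        assert emb.n_dims == 3


class TestRefineGeneModel:
    def _embedding(self, loadings):
        loadings = np.asarray(loadings, dtype=float)
        return Embedding(
            coordinates=np.zeros((2, loadings.shape[1])),
            component_sdev=np.ones(loadings.shape[1]),
            loadings=loadings,
            genes=[f"G{i}" for i in range(loadings.shape[0])],
        )

    def test_top_and_bottom_by_signed_loading(self):
        emb = self._embedding([[0.9], [0.1], [-0.8]])
        genes = refine_gene_model(emb, PcaRefineConfig(1, 1, 1))
        assert genes == ["G0", "G2"]

    def test_gene_in_multiple_dims_appears_once(self):
        emb = self._embedding([[0.9, -0.9], [0.1, 0.8], [-0.8, 0.1]])
        genes = refine_gene_model(emb, PcaRefineConfig(2, 1, 1))
        assert genes == ["G0", "G2", "G1"]
        assert len(genes) == len(set(genes))

    def test_counts_without_overlap(self, rng):
        # 80 genes, 2 dims engineered so top/bottom 20 of each dim are disjoint
        loadings = np.zeros((80, 2))
        loadings[:20, 0] = np.linspace(2, 1, 20)
        loadings[20:40, 0] = np.linspace(-1, -2, 20)
        loadings[40:60, 1] = np.linspace(2, 1, 20)
        loadings[60:80, 1] = np.linspace(-1, -2, 20)
        emb = self._embedding(loadings)
        genes = refine_gene_model(emb, PcaRefineConfig(2, 20, 20))
        assert len(genes) == 80

    def test_fewer_dims_than_scan_warns(self):
        emb = self._embedding([[0.5], [-0.5]])
        with pytest.warns(UserWarning, match="dims"):
            refine_gene_model(emb, PcaRefineConfig(10, 1, 1))


class TestTwoRoundPca:
    def test_refinement_covering_all_genes_reproduces_round_one(self, rng):
        # when the refined set equals the model set, round 2 equals round 1
        # up to component sign and gene order
        X = np.abs(rng.normal(2, 1, size=(6, 40))) + 0.5
        stats = pd.DataFrame(
            {
                "base_mean": X.mean(axis=1),
                "coverage": (X > 0).sum(axis=1),
                "dispersion": np.full(6, 9.0),
            },
            index=pd.Index([f"G{i}" for i in range(6)], name="gene"),
        )
        gm = GeneModelConfig(top_coverage=6, min_dispersion=1.0)
        refine = PcaRefineConfig(n_dims_scan=3, top_k=6, bottom_k=6)
        emb2 = two_round_pca(X, stats, gm, refine, n_pcs=3)
        genes1 = select_model_genes(stats, gm)
        emb1 = pca(X, genes1, 3)
        assert set(emb2.genes) == set(genes1)
        assert np.abs(emb2.coordinates) == pytest.approx(
            np.abs(emb1.coordinates), abs=1e-8
        )


class TestKmeansSilhouette:
    def _clouds(self, rng, centers, n_per=40, sigma=0.1):
        points, labels = [], []
        for i, c in enumerate(centers):
            points.append(rng.normal(c, sigma, size=(n_per, len(c))))
            labels += [i] * n_per
        X = np.vstack(points)
        emb = Embedding(
            coordinates=X,
            component_sdev=np.sort(X.std(axis=0))[::-1],
            loadings=np.zeros((2, X.shape[1])),
            genes=["a", "b"],
        )
        return emb, np.array(labels)

    def test_two_separated_clouds_select_k2(self, rng):
        emb, truth = self._clouds(rng, [(0, 0), (10, 10)])
        res = cluster_kmeans_silhouette(
            emb, ClusterConfig(n_pcs=2, k_min=2, k_max=6, seed=0)
        )
        assert res.k == 2
        assert adjusted_rand_score(truth, res.labels) == 1.0
        assert set(res.labels) == {1, 2}

    def test_four_equidistant_clouds_select_k4(self, rng):
        emb, truth = self._clouds(rng, [(0, 0), (0, 20), (20, 0), (20, 20)])
        res = cluster_kmeans_silhouette(
            emb, ClusterConfig(n_pcs=2, k_min=2, k_max=8, seed=0)
        )
        assert res.k == 4
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_single_k_scan(self, rng):
        emb, _ = self._clouds(rng, [(0, 0), (8, 8), (16, 0)])
        res = cluster_kmeans_silhouette(
            emb, ClusterConfig(n_pcs=2, k_min=3, k_max=3, seed=0)
        )
        assert res.k == 3
        assert len(res.silhouette_by_k) == 1

    def test_reported_silhouette_matches_loop_oracle(self, rng):
        emb, _ = self._clouds(rng, [(0, 0), (6, 6)], n_per=25, sigma=0.5)
        res = cluster_kmeans_silhouette(
            emb, ClusterConfig(n_pcs=2, k_min=2, k_max=2, seed=0)
        )
        oracle = silhouette_by_loops(
            emb.coordinates.tolist(), res.labels.tolist()
        )
        assert res.mean_silhouette == pytest.approx(oracle, rel=1e-9)

    def test_degenerate_embedding_raises(self):
        emb = Embedding(
            coordinates=np.ones((10, 3)),
            component_sdev=np.zeros(3),
            loadings=np.zeros((2, 3)),
            genes=["a", "b"],
        )
        with pytest.raises(NoClusterStructureError):
            cluster_kmeans_silhouette(emb)


class TestEmbed2d:
    def _embedding(self, rng, n=30, d=5):
        return Embedding(
            coordinates=rng.normal(size=(n, d)),
            component_sdev=np.ones(d),
            loadings=np.zeros((3, d)),
            genes=["a", "b", "c"],
        )

    @pytest.mark.parametrize("method", ["umap", "tsne"])
    def test_shape_finiteness_and_determinism(self, rng, method):
        emb = self._embedding(rng)
        out1 = embed_2d(emb, method=method, seed=7)
        out2 = embed_2d(emb, method=method, seed=7)
        assert out1.shape == (30, 2)
        assert np.all(np.isfinite(out1))
        assert out1 == pytest.approx(out2)

    def test_minimal_input(self, rng):
        emb = self._embedding(rng, n=3, d=2)
        out = embed_2d(emb, method="tsne", seed=1)
        assert out.shape == (3, 2)

    def test_unknown_method_raises(self, rng):
        with pytest.raises(ConfigError):
            embed_2d(self._embedding(rng), method="pca-magic", seed=0)
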