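import numpy as np
import pandas as pd
import pytest

from conftest import make_vdj, repertoire_vdj
from oracles import clonality_by_enumeration
from tilscope.clonotype import (
    build_clonotypes,
    clonality_report,
    compare_clonotype_richness,
    frequency_partition,
    link_clonotypes_to_phenotypes,
    top_n_share,
    upper_quintile_clonotypes,
)
from tilscope.errors import TilscopeError
from tilscope.phenotype import PhenotypeAssignment
from tilscope.tenx_io import BarcodeMap


class TestBuildClonotypes:
    def test_paired_and_single_chain_cells(self):
        vdj = make_vdj(
            [
                ("b1", "TRA", "CAX", True),
                ("b1", "TRB", "CASSY", True),
                ("b2", "TRA", "CAX", True),
                ("b2", "TRB", "CASSY", True),
                ("b3", "TRB", "CASSZ", True),
            ]
        )
        summary = build_clonotypes(vdj)
        assert summary.n_clonotypes == 2
        assert summary.table["frequency"].tolist() == [2, 1]
        assert summary.table["freq_class"].tolist() == ["doubleton", "singleton"]
        assert summary.table["key"].iloc[0] == "TRA:CAX;TRB:CASSY"

    def test_double_beta_cell_keeps_both_tokens(self):
        vdj = make_vdj(
            [("b1", "TRB", "CASSA", True), ("b1", "TRB", "CASSB", True)]
        )
        summary = build_clonotypes(vdj)
        assert summary.table["key"].iloc[0] == "TRB:CASSA;TRB:CASSB"

    def test_unproductive_cells_excluded_and_counted(self):
        vdj = make_vdj(
            [
                ("b1", "TRB", "CASSA", True),
                ("b2", "TRB", "CASSB", False),
                ("b3", "IGH", "CARX", True),
            ]
        )
        summary = build_clonotypes(vdj)
        assert summary.n_clonotypes == 1
        assert summary.n_excluded == 2

    def test_raw_id_mode_without_ids_raises(self):
        vdj = make_vdj([("b1", "TRB", "CASSA", True)])
        vdj.df["raw_clonotype_id"] = ""
        with pytest.raises(TilscopeError, match="cdr3_pair"):
            build_clonotypes(vdj, mode="raw_id")

    def test_umi_weighted_mode(self):
        vdj = make_vdj([("b1", "TRB", "CASSA", True), ("b2", "TRB", "CASSB", True)])
        vdj.df.loc[0, "umis"] = 9
        summary = build_clonotypes(vdj, weight="umis")
        assert summary.table["frequency"].tolist() == [9, 1]
        assert summary.n_cells == 10


class TestRepertoireStatistics:
    def test_partition_of_hand_built_spectrum(self):
        # 10 cells: {A:4, B:2, C..F:1 x4} -> A=40%, doubletons=20%, singletons=40%
        assignment = [0, 0, 0, 0, 1, 1, 2, 3, 4, 5]
        summary = build_clonotypes(repertoire_vdj(assignment))
        part = frequency_partition(summary).set_index("category")["percent"]
        assert part["clonotype_1"] == pytest.approx(40.0)
        assert part["doubletons"] == pytest.approx(20.0)
        assert part["singletons"] == pytest.approx(40.0)
        assert part["other"] == pytest.approx(0.0)
        assert part.sum() == pytest.approx(100.0, abs=1e-9)

    def test_partition_has_no_zero_padded_ranks(self):
        summary = build_clonotypes(repertoire_vdj([0, 0, 0, 1, 1, 1]))
        categories = frequency_partition(summary)["category"].tolist()
        assert categories == ["clonotype_1", "clonotype_2", "other", "doubletons", "singletons"]

    def test_all_singletons(self):
        summary = build_clonotypes(repertoire_vdj(list(range(7))))
        part = frequency_partition(summary).set_index("category")["percent"]
        assert part["singletons"] == pytest.approx(100.0)

    @pytest.mark.parametrize(
        "assignment, n, expected",
        [
            ([0, 0, 0, 0, 1, 1, 2, 3, 4, 5], 2, 60.0),
            ([0, 0, 0, 0, 1, 1, 2, 3, 4, 5], 99, 100.0),
            (list(range(10)), 10, 100.0),
            (list(range(10)), 1, 10.0),
        ],
    )
    def test_top_n_share(self, assignment, n, expected):
        summary = build_clonotypes(repertoire_vdj(assignment))
        assert top_n_share(summary, n) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "assignment, expected",
        [
            ([0, 0, 0, 0, 1, 1, 2, 3, 4, 5], 1),  # freq-4 clone covers 2 cells
            (list(range(10)), 2),  # 10 singletons, quintile of 2
            (list(range(5)), 1),  # quintile of 1
        ],
    )
    def test_upper_quintile(self, assignment, expected):
        summary = build_clonotypes(repertoire_vdj(assignment))
        assert upper_quintile_clonotypes(summary) == expected

    def test_top_n_share_monotone_in_n(self, rng):
        assignment = rng.integers(0, 40, size=200).tolist()
        summary = build_clonotypes(repertoire_vdj(assignment))
        shares = [top_n_share(summary, n) for n in range(1, 41)]
        assert all(a <= b + 1e-12 for a, b in zip(shares, shares[1:]))

    def test_merging_clonotypes_never_increases_quintile_count(self, rng):
        for _ in range(10):
            assignment = rng.integers(0, 30, size=120).tolist()
            before = upper_quintile_clonotypes(
                build_clonotypes(repertoire_vdj(assignment))
            )
            merged = [0 if c == 1 else c for c in assignment]  # merge 1 into 0
            after = upper_quintile_clonotypes(
                build_clonotypes(repertoire_vdj(merged))
            )
            assert after <= before

    def test_class_counts_partition_all_clonotypes(self, rng):
        assignment = rng.integers(0, 60, size=300).tolist()
        summary = build_clonotypes(repertoire_vdj(assignment))
        counts = summary.table["freq_class"].value_counts()
        assert counts.sum() == summary.n_clonotypes

    def test_all_statistics_match_enumeration_oracle(self, rng):
        for _ in range(25):
            n_cells = int(rng.integers(1, 500))
            n_pool = int(rng.integers(1, max(2, n_cells)))
            assignment = rng.integers(0, n_pool, size=n_cells).tolist()
            summary = build_clonotypes(repertoire_vdj(assignment))
            oracle = clonality_by_enumeration(assignment)
            report = clonality_report(summary)
            assert report.n_clonotypes == len(oracle["freq"])
            assert report.n_singletons == oracle["n_singletons"]
            assert report.n_doubletons == oracle["n_doubletons"]
            assert report.top10_share == pytest.approx(oracle["top_share"](10))
            assert report.upper_quintile_clonotypes == oracle["upper_quintile"]
            part = frequency_partition(summary).set_index("category")["percent"]
            for category, pct in oracle["partition"].items():
                assert part[category] == pytest.approx(pct)


class TestLinkage:
    def _assignment(self, barcode_phenos):
        return PhenotypeAssignment(
            cluster_labels={},
            cluster_scores=pd.DataFrame(),
            cell_labels=np.array([p for _, p in barcode_phenos], dtype=object),
            barcodes=[b for b, _ in barcode_phenos],
        )

    def _identity_map(self, barcodes):
        return BarcodeMap({b: b for b in barcodes}, 0, 0)

    def test_pure_clonotype_not_spanning(self):
        vdj = make_vdj([(f"b{i}", "TRB", "CASSA", True) for i in range(5)])
        summary = build_clonotypes(vdj)
        assignment = self._assignment([(f"b{i}", "cytotoxic") for i in range(5)])
        linked = link_clonotypes_to_phenotypes(
            summary, assignment, self._identity_map(assignment.barcodes)
        )
        assert linked["cytotoxic"].iloc[0] == 5
        assert not linked["spanning"].iloc[0]

    def test_half_and_half_clonotype_spans(self):
        vdj = make_vdj([(f"b{i}", "TRB", "CASSA", True) for i in range(4)])
        summary = build_clonotypes(vdj)
        assignment = self._assignment(
            [("b0", "naive"), ("b1", "naive"), ("b2", "cytotoxic"), ("b3", "cytotoxic")]
        )
        linked = link_clonotypes_to_phenotypes(
            summary, assignment, self._identity_map(assignment.barcodes)
        )
        assert linked["spanning"].iloc[0]

    def test_unmatched_barcodes_counted(self):
        vdj = make_vdj([("b0", "TRB", "CASSA", True), ("b1", "TRB", "CASSA", True)])
        summary = build_clonotypes(vdj)
        assignment = self._assignment([("b0", "naive")])
        linked = link_clonotypes_to_phenotypes(
            summary, assignment, BarcodeMap({"b0": "b0"}, 0, 1)
        )
        assert linked["n_matched"].iloc[0] == 1
        assert linked["n_unmatched"].iloc[0] == 1


class TestRichness:
    def test_identical_groups(self):
        result = compare_clonotype_richness([100, 100], [100, 100])
        assert result.mean_a == result.mean_b == 100
        assert result.p_value == 1.0

    def test_group_means(self):
        result = compare_clonotype_richness([1000, 1200], [500, 600])
        assert result.mean_a == pytest.approx(1100)
        assert result.mean_b == pytest.approx(550)
        assert result.computable

    def test_single_sample_group_flagged(self):
        result = compare_clonotype_richness([800], [500, 600])
        assert not result.computable
        assert result.p_value is None

    def test_accepts_summaries(self):
        summaries = [build_clonotypes(repertoire_vdj([0, 1, 2]))]
        result = compare_clonotype_richness(summaries, [3])
        assert result.mean_a == 3.0
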