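import numpy as np
import pandas as pd
import pytest

from conftest import gaussian_bumps
from nucposer.genomic_io import CoverageTrack, GeneModel
from nucposer.integration import (
    ConservationClass,
    DEClass,
    ExpressionRecord,
    build_gene_table,
    classify_conservation,
    classify_de,
    co_occupancy_fraction,
    enrichment_matrix,
    median_profile,
    rpkm_log2,
    stratified_counts,
    venn_counts,
)
from nucposer.nucleosome_map import NucleosomePeak, PlusOneCall


class TestRpkmLog2:
    def test_formula_identity(self):
        assert rpkm_log2(100, 1000, 1e6, pseudocount=0) == pytest.approx(np.log2(100))

    def test_zero_count_with_unit_pseudocount(self):
        assert rpkm_log2(0, 1000, 1e6, pseudocount=1) == 0.0

    def test_scale_invariance(self):
        a = rpkm_log2(100, 1500, 2e6)
        b = rpkm_log2(200, 1500, 4e6)
        assert a == pytest.approx(b)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            rpkm_log2(1, 0, 1e6)
        with pytest.raises(ValueError):
            rpkm_log2(1, 1000, 0)


class TestClassifyDE:
    @pytest.mark.parametrize(
        "fc,p,expected",
        [
            (1.0, 0.005, DEClass.UP),      # boundary fold change counts
            (-1.0, 0.005, DEClass.DOWN),
            (-2.3, 1e-4, DEClass.DOWN),
            (3.0, 0.02, DEClass.NS),       # p fails
            (0.5, 1e-6, DEClass.NS),       # fold change fails
        ],
    )
    def test_classes(self, fc, p, expected):
        rec = ExpressionRecord("g", {}, fc, p)
        assert classify_de(rec) is expected

    def test_missing_p_rejected(self):
        rec = ExpressionRecord("g", {}, 2.0, float("nan"))
        with pytest.raises(ValueError):
            classify_de(rec)


class TestSetSummaries:
    def test_two_set_venn(self):
        counts = venn_counts({1, 2, 3}, {2, 3, 4})
        assert counts == {"A": 1, "B": 1, "A&B": 2}

    def test_disjoint_sets(self):
        assert venn_counts({1}, {2})["A&B"] == 0

    def test_three_set_regions_partition_the_union(self):
        a, b, c = {1, 2, 3, 4}, {3, 4, 5}, {4, 5, 6, 7}
        counts = venn_counts(a, b, c)
        assert sum(counts.values()) == len(a | b | c)
        assert counts["A&B&C"] == 1

    def test_co_occupancy_fraction(self):
        ref = {f"g{i}" for i in range(100)}
        mark = {f"g{i}" for i in range(36)} | {"x1", "x2"}
        assert co_occupancy_fraction(ref, mark) == pytest.approx(0.36)
        assert co_occupancy_fraction({"a"}, {"a", "b"}) == 1.0
        with pytest.raises(ValueError):
            co_occupancy_fraction(set(), {"a"})

    def test_co_occupancy_matches_membership_oracle(self):
        rng = np.random.default_rng(2)
        ref = set(rng.choice(200, 80, replace=False))
        mark = set(rng.choice(200, 50, replace=False))
        oracle = sum(1 for g in ref if g in mark) / len(ref)
        assert co_occupancy_fraction(ref, mark) == oracle


class TestEnrichmentMatrix:
    def _setup(self):
        cov = np.arange(10000, dtype=float)
        track = CoverageTrack({"c": cov})
        genes = {
            "short": GeneModel("short", "c", 2000, 2300, "+"),
            "long": GeneModel("long", "c", 5000, 5500, "+"),
        }
        calls = [
            PlusOneCall("long", plus_one=NucleosomePeak("c", 5030, 40)),
            PlusOneCall("short", plus_one=NucleosomePeak("c", 2030, 40)),
        ]
        return track, calls, genes

    def test_row_is_coverage_slice(self):
        track, calls, genes = self._setup()
        mat, ids = enrichment_matrix(track, calls, genes, flank_up=1000, flank_down=5000)
        row = mat[ids.index("short")]
        assert np.array_equal(row, np.arange(2030 - 1000, 2030 + 5000, dtype=float))

    def test_rows_sorted_by_increasing_gene_length(self):
        track, calls, genes = self._setup()
        _, ids = enrichment_matrix(track, calls, genes, 100, 200)
        assert ids == ["short", "long"]

    def test_minus_strand_row_is_reversed_window(self):
        cov = np.arange(10000, dtype=float)
        track = CoverageTrack({"c": cov})
        genes = {"m": GeneModel("m", "c", 4000, 6000, "-")}
        calls = [PlusOneCall("m", plus_one=NucleosomePeak("c", 5970, 40))]
        mat, _ = enrichment_matrix(track, calls, genes, flank_up=100, flank_down=300)
        # oriented offsets -100..299 map to chromosome 5970+100 .. 5970-299
        expected = np.arange(5970 + 100, 5970 - 300, -1, dtype=float)
        assert np.array_equal(mat[0], expected)

    def test_genes_without_plus_one_excluded_and_offgenome_is_nan(self):
        track = CoverageTrack({"c": np.ones(1000)})
        genes = {"a": GeneModel("a", "c", 100, 400, "+"),
                 "b": GeneModel("b", "c", 500, 900, "+")}
        calls = [PlusOneCall("a", plus_one=NucleosomePeak("c", 130, 40)),
                 PlusOneCall("b")]
        mat, ids = enrichment_matrix(track, calls, genes, flank_up=200, flank_down=100)
        assert ids == ["a"]
        assert np.isnan(mat[0][:70]).all() and (mat[0][70:] == 1).all()


class TestMedianProfile:
    def test_constant_matrix(self):
        assert np.allclose(median_profile(np.full((4, 42), 5.0), 21), [5.0, 5.0])

    def test_median_robust_to_one_outlier_row(self):
        mat = np.full((11, 21), 3.0)
        mat[5] = 1e6
        assert median_profile(mat, 21)[0] == 3.0

    def test_nan_handling_and_partial_bin(self):
        mat = np.array([[1.0, np.nan, 2.0, 7.0, np.nan]])
        prof = median_profile(mat, 2)
        assert prof[0] == 1.0 and prof[1] == pytest.approx(4.5) and np.isnan(prof[2])

    def test_phased_array_keeps_repeat_spacing(self):
        """Profile maxima of a planted phased array stay one repeat apart."""
        repeat = 165
        centers = np.arange(300, 2500, repeat)
        rows = [gaussian_bumps(2800, centers + off, [30] * len(centers), sigma=40)
                for off in (-3, 0, 3)]
        prof = median_profile(np.array(rows), bin_width=1)
        # periodicity via autocorrelation: the first off-zero peak sits at the
        # nucleosome repeat length
        x = prof - prof.mean()
        ac = np.correlate(x, x, mode="full")[len(x) - 1 :]
        lag = 100 + int(np.argmax(ac[100:231]))
        assert abs(lag - repeat) <= 2

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            median_profile(np.zeros((2, 10)), 0)


class TestConservation:
    @staticmethod
    def _rows(n_hits, pident=80.0):
        return pd.DataFrame(
            {"sseqid": [f"s{i}" for i in range(n_hits)], "pident": [pident] * n_hits}
        )

    def test_low_and_high_classes(self):
        assert classify_conservation(self._rows(30)) == (ConservationClass.LOW, 30)
        assert classify_conservation(self._rows(350)) == (ConservationClass.HIGH, 350)
        assert classify_conservation(self._rows(100))[0] is ConservationClass.INTERMEDIATE

    def test_identity_filter_removes_weak_hits(self):
        cls, hits = classify_conservation(self._rows(100, pident=35.0))
        assert hits == 0 and cls is ConservationClass.LOW

    def test_distinct_subjects_counted_once(self):
        rows = pd.DataFrame({"sseqid": ["s1"] * 60, "pident": [90.0] * 60})
        assert classify_conservation(rows)[1] == 1

    def test_malformed_rows_rejected(self):
        with pytest.raises(ValueError):
            classify_conservation(pd.DataFrame({"pident": [50.0]}))


class TestGeneTable:
    def _genes(self, n=4):
        return [GeneModel(f"g{i}", "c", 1000 * i + 100, 1000 * i + 800, "+")
                for i in range(n)]

    def test_full_join_has_all_columns(self):
        genes = self._genes()
        occ = pd.DataFrame(
            [{"gene_id": g.gene_id, "mark": m, "positive": True, "negative_class": False}
             for g in genes for m in ("H2A.Z", "H3K27me3")]
        )
        calls = [PlusOneCall(g.gene_id, plus_one=NucleosomePeak("c", g.start + 30, 40))
                 for g in genes]
        expr = pd.DataFrame(
            {"gene_id": [g.gene_id for g in genes],
             "rpkm_log2_wt": [6.0, 5.0, 0.4, 3.0],
             "log2fc": [-3.0, 0.1, 0.0, 2.0],
             "p_value": [1e-5, 0.5, 0.9, 1e-4]}
        )
        table = build_gene_table(genes, occupancy=occ, plusone_calls=calls,
                                 expression=expr)
        assert len(table) == 4
        assert table["de_class"].tolist() == ["down", "ns", "ns", "up"]
        assert table["expressed_wt"].tolist() == [True, True, False, True]
        assert table["occ_H2A.Z"].all() and table["plus_one_present"].all()

    def test_gene_missing_from_expression_keeps_row(self):
        genes = self._genes(2)
        expr = pd.DataFrame({"gene_id": ["g0"], "rpkm_log2_wt": [6.0],
                             "log2fc": [0.0], "p_value": [0.5]})
        table = build_gene_table(genes, expression=expr).set_index("gene_id")
        assert pd.isna(table.loc["g1", "de_class"])
        assert table.loc["g0", "de_class"] == "ns"

    def test_duplicate_inputs_rejected(self):
        genes = self._genes(2)
        expr = pd.DataFrame({"gene_id": ["g0", "g0"], "rpkm_log2_wt": [1, 2],
                             "log2fc": [0, 0], "p_value": [0.5, 0.5]})
        with pytest.raises(ValueError):
            build_gene_table(genes, expression=expr)

    def test_de_partition_is_complete(self, default_dataset, default_result):
        """Every gene with expression evidence falls in exactly one DE class."""
        table = default_result.gene_table
        counts = table["de_class"].value_counts()
        assert counts.sum() == table["p_value"].notna().sum()

    def test_stratified_counts_match_truth(self, default_dataset, default_result):
        table = default_result.gene_table
        strata = stratified_counts(table, mark="H3K27me3")
        truth = default_dataset.truth
        planted = len(truth[truth["class_label"] == "h2az_k27"])
        got = strata.loc[
            strata["occ_H2A.Z"] & strata["occ_H3K27me3"] & (strata["de_class"] == "down"),
            "n_genes",
        ].sum()
        assert got >= 0.9 * planted
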