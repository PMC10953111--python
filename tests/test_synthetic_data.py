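import numpy as np
import pandas as pd
import pytest

from nucposer.chip_occupancy import DEFAULT_MARK_CONFIGS, call_mark
from nucposer.genomic_io import filter_fragments_by_length
from nucposer.integration import ExpressionRecord, classify_de
from nucposer.synthetic_data import (
    CHROMATIN_CLASSES,
    SimConfig,
    generate_annotation,
    plant_chromatin,
    simulate_chip,
    simulate_expression,
    simulate_mnase,
)

SMALL = SimConfig(n_genes=60, chrom_length=400_000, seed=7)


@pytest.fixture(scope="module")
def small_ann():
    return generate_annotation(SMALL)


@pytest.fixture(scope="module")
def small_truth(small_ann):
    return plant_chromatin(small_ann, SMALL)


class TestGenerateAnnotation:
    def test_same_seed_gives_byte_identical_gff3(self, tmp_path, small_ann):
        p1, p2 = tmp_path / "a.gff3", tmp_path / "b.gff3"
        small_ann.write(p1)
        generate_annotation(SMALL).write(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_divergent_pair_bookkeeping(self, small_ann):
        expected_pairs = round(SMALL.divergent_fraction * SMALL.n_genes)
        assert len(small_ann.pairs) == expected_pairs
        by_id = small_ann.genes_by_id
        for a, b in small_ann.pairs:
            ga, gb = by_id[a], by_id[b]
            assert (ga.strand, gb.strand) == ("-", "+")
            assert gb.atg - ga.atg == SMALL.pair_atg_gap

    def test_unit_spacing_at_least_2kb(self, small_ann):
        paired = {g for pair in small_ann.pairs for g in pair}
        genes = sorted(small_ann.genes, key=lambda g: (g.chrom, g.start))
        for prev, cur in zip(genes, genes[1:]):
            if cur.chrom != prev.chrom:
                continue
            if prev.gene_id in paired and (prev.gene_id, cur.gene_id) in small_ann.pairs:
                continue  # pair members share a promoter by design
            assert cur.start - prev.end >= 2000

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError):
            generate_annotation(SimConfig(n_genes=200, chrom_length=50_000))


class TestPlantChromatin:
    def test_class_counts_within_3_sigma_of_multinomial(self):
        props = {"h2az_k4": 0.2, "h2az_k27": 0.1, "k27_only": 0.3,
                 "h2az_only": 0.2, "unmarked": 0.2}
        cfg = SimConfig(n_genes=1000, chrom_length=5_000_000, seed=3,
                        divergent_fraction=0.0, class_proportions=props)
        truth = plant_chromatin(generate_annotation(cfg), cfg)
        counts = truth["class_label"].value_counts()
        for cls in CHROMATIN_CLASSES:
            p = props[cls]
            sigma = np.sqrt(1000 * p * (1 - p))
            assert abs(counts.get(cls, 0) - 1000 * p) <= 3 * sigma

    def test_k27_domains_span_at_least_3_adjacent_genes(self, small_truth):
        k27 = small_truth[small_truth["k27"]]
        assert len(k27) > 0
        for _, sub in k27.groupby("k27_domain"):
            assert len(sub) >= 3
            idx = sub.index.to_numpy()
            assert np.all(np.diff(np.sort(idx)) == 1)  # adjacent in gene order

    def test_all_unmarked_config_still_plants_plus_one(self):
        props = {"h2az_k4": 0.0, "h2az_k27": 0.0, "k27_only": 0.0,
                 "h2az_only": 0.0, "unmarked": 1.0}
        cfg = SimConfig(n_genes=40, chrom_length=300_000, seed=5,
                        class_proportions=props)
        truth = plant_chromatin(generate_annotation(cfg), cfg)
        assert not truth[["h2az", "k4", "k27"]].any().any()
        assert truth["plus_one_pos"].notna().all()

    def test_pair_members_share_promoter_nucleosome(self, small_ann, small_truth):
        t = small_truth.set_index("gene_id")
        for a, b in small_ann.pairs:
            assert t.loc[a, "minus_one_pos"] == t.loc[b, "plus_one_pos"]
            assert t.loc[b, "minus_one_pos"] == t.loc[a, "plus_one_pos"]
            assert t.loc[a, "class_label"] == t.loc[b, "class_label"]


class TestSimulateMnase:
    def test_seed_determinism(self, small_ann, small_truth):
        f1 = simulate_mnase(small_ann, small_truth, SMALL)
        f2 = simulate_mnase(small_ann, small_truth, SMALL)
        assert f1.df.equals(f2.df)

    def test_length_filter_retains_central_mass(self, small_ann, small_truth):
        """The 130-170 bp filter keeps the normal-CDF mass of N(147, 8)."""
        frags = simulate_mnase(small_ann, small_truth, SMALL)
        kept = filter_fragments_by_length(frags, 130, 170)
        n = len(frags)
        # P(130 <= X <= 170) for X ~ N(147, 8), discretized by rounding
        from math import erf, sqrt

        def phi(x):
            return 0.5 * (1 + erf(x / sqrt(2)))

        p = phi((170.5 - 147) / 8) - phi((129.5 - 147) / 8)
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(len(kept) - n * p) <= 3 * sigma

    def test_isolated_nucleosome_fragments_cover_dyad(self):
        cfg = SimConfig(n_genes=1, chrom_length=50_000, seed=9,
                        divergent_fraction=0.0, bg_fragment_fraction=0.0)
        ann = generate_annotation(cfg)
        truth = plant_chromatin(ann, cfg)
        frags = simulate_mnase(ann, truth, cfg)
        dyad_candidates = set()
        g = ann.genes[0]
        t = cfg.plus_one_offset
        sign = 1 if g.strand == "+" else -1
        while t <= g.length - 73:
            dyad_candidates.add(g.atg + sign * t)
            t += cfg.nucleosome_repeat
        up = cfg.plus_one_offset - cfg.peak_separation
        dyad_candidates |= {g.atg + sign * up, g.atg + sign * (up - cfg.nucleosome_repeat)}
        for _, row in frags.df.iterrows():
            mid = (row.start + row.end) / 2
            assert min(abs(mid - d) for d in dyad_candidates) <= 5 * cfg.frag_jitter_sd


class TestSimulateChip:
    def test_unknown_mark_rejected(self, small_ann, small_truth):
        with pytest.raises(ValueError):
            simulate_chip(small_ann, small_truth, SMALL, "H4K16ac")

    def test_unit_fold_is_indistinguishable_from_background(self, small_ann, small_truth):
        cfg = SimConfig(n_genes=SMALL.n_genes, chrom_length=SMALL.chrom_length,
                        seed=SMALL.seed, enrichment_fold={"H2A.Z": 1.0,
                                                          "H3K4me3": 1.0,
                                                          "H3K27me3": 1.0})
        track = simulate_chip(small_ann, small_truth, cfg, "H2A.Z")[0]
        vals = track.values("chr1")
        background = cfg.background_rel * DEFAULT_MARK_CONFIGS["H2A.Z"].threshold
        # mean of n iid Poisson(bg) draws: 3-sigma band around bg
        sigma = np.sqrt(background / len(vals))
        assert abs(vals.mean() - background) <= 3 * sigma

    def test_marked_gene_called_positive(self, small_ann, small_truth):
        tracks = simulate_chip(small_ann, small_truth, SMALL, "H2A.Z")
        cfg = DEFAULT_MARK_CONFIGS["H2A.Z"]
        by_id = small_ann.genes_by_id
        marked = small_truth.loc[small_truth["h2az"], "gene_id"]
        hits = sum(call_mark(tracks, by_id[g], cfg).positive for g in marked)
        assert hits >= 0.95 * len(marked)

    def test_replicates_differ_but_agree_on_truth_windows(self, small_ann, small_truth):
        t1, t2 = simulate_chip(small_ann, small_truth, SMALL, "H3K27me3")
        v1, v2 = t1.values("chr1"), t2.values("chr1")
        assert not np.array_equal(v1, v2)  # independent noise
        marked = small_truth.loc[small_truth["k27"], "gene_id"]
        by_id = small_ann.genes_by_id
        for g in marked:
            gene = by_id[g]
            m1 = v1[gene.start:gene.end].mean()
            m2 = v2[gene.start:gene.end].mean()
            assert abs(m1 - m2) / m1 < 0.1


class TestSimulateExpression:
    def test_seed_determinism(self, small_ann, small_truth):
        e1 = simulate_expression(small_ann, small_truth, SMALL)
        e2 = simulate_expression(small_ann, small_truth, SMALL)
        assert e1.equals(e2)

    def test_planted_flips_classify_down(self, small_ann, small_truth):
        expr = simulate_expression(small_ann, small_truth, SMALL).set_index("gene_id")
        flips = small_truth.loc[small_truth["flips_down"], "gene_id"]
        assert len(flips) > 0
        down = sum(
            classify_de(ExpressionRecord(g, {}, expr.loc[g, "log2fc"],
                                         expr.loc[g, "p_value"])).value == "down"
            for g in flips
        )
        assert down >= 0.95 * len(flips)

    def test_stable_genes_mostly_ns(self, small_ann, small_truth):
        expr = simulate_expression(small_ann, small_truth, SMALL).set_index("gene_id")
        stable = small_truth.loc[~small_truth["flips_down"], "gene_id"]
        ns = sum(
            classify_de(ExpressionRecord(g, {}, expr.loc[g, "log2fc"],
                                         expr.loc[g, "p_value"])).value == "ns"
            for g in stable
        )
        # non-flip genes are ns except the ~1% uniform-p false positives
        assert ns >= 0.95 * len(stable)
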