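import math

import numpy as np
import pytest

from loopgene.core_io import DataError, GenomicInterval, Loop, Peak
from loopgene.loci import Variant
from loopgene.metrics import (
    eqtl_validation,
    interactions_per_gene,
    loop_distance_stats,
    loop_set_concordance,
    snp_peak_enrichment,
    tad_overlap_stats,
)
from conftest import make_tss, random_instance
from _oracles import bf_interactions_per_gene, bf_loop_set_concordance, bf_lower_median


def mk_loop(chrom, s1, e1, s2, e2, sample="s0"):
    return Loop(GenomicInterval(chrom, s1, e1), GenomicInterval(chrom, s2, e2),
                sample_id=sample)


class TestEqtlValidation:
    def test_set_arithmetic(self):
        vr = eqtl_validation({"L1": {"A", "B", "C"}}, {"L1": {"B", "C", "D"}})
        assert (vr.n_intersection, vr.n_eqtl_genes, vr.n_linked_genes) == (2, 3, 3)
        assert vr.recall == pytest.approx(2 / 3)
        assert vr.precision == pytest.approx(2 / 3)

    def test_identity_gives_perfect_scores(self):
        sets = {"L1": {"A"}, "L2": {"B", "C"}}
        vr = eqtl_validation(sets, sets)
        assert vr.recall == 1.0 and vr.precision == 1.0

    def test_one_sided_loci_enter_denominators_only(self):
        vr = eqtl_validation({"L1": {"A"}}, {"L2": {"B", "C"}})
        assert vr.n_intersection == 0
        assert vr.n_eqtl_genes == 2 and vr.n_linked_genes == 1

    def test_per_locus_matching_differs_from_global_union(self):
        linked = {"L1": {"A"}, "L2": {"B"}}
        eqtl = {"L1": {"B"}, "L2": {"A"}}
        assert eqtl_validation(linked, eqtl).n_intersection == 0
        assert eqtl_validation(linked, eqtl, per_locus=False).n_intersection == 2

    def test_empty_eqtl_mapping_is_an_error(self):
        with pytest.raises(DataError):
            eqtl_validation({"L1": {"A"}}, {})

    def test_identities_recomputed_from_counts(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(30)]
        for _ in range(20):
            linked = {f"L{i}": set(rng.choice(genes, size=rng.integers(0, 6), replace=False))
                      for i in range(5)}
            eqtl = {f"L{i}": set(rng.choice(genes, size=rng.integers(1, 6), replace=False))
                    for i in range(5)}
            vr = eqtl_validation(linked, eqtl)
            assert vr.recall == pytest.approx(vr.n_intersection / vr.n_eqtl_genes)
            if vr.n_linked_genes:
                assert vr.precision == pytest.approx(vr.n_intersection / vr.n_linked_genes)


class TestTadOverlap:
    TADS = [GenomicInterval("c1", 0, 1_000_000), GenomicInterval("c1", 1_000_000, 2_000_000)]

    def test_within_and_crossing(self):
        within = mk_loop("c1", 10_000, 15_000, 500_000, 505_000)
        crossing = mk_loop("c1", 900_000, 905_000, 1_100_000, 1_105_000)
        stats = tad_overlap_stats([within, crossing], self.TADS)
        assert (stats.n_within, stats.n_crossing) == (1, 1)
        assert stats.fraction_within == 0.5

    def test_anchor_straddling_boundary_counts_as_crossing(self):
        straddle = mk_loop("c1", 10_000, 15_000, 995_000, 1_005_000)
        stats = tad_overlap_stats([straddle], self.TADS)
        assert stats.n_crossing == 1

    def test_counts_cover_all_intrachromosomal_loops(self):
        inter = Loop(GenomicInterval("c1", 0, 5_000), GenomicInterval("c2", 0, 5_000))
        loops = [mk_loop("c1", 1_000, 2_000, 3_000, 4_000), inter]
        stats = tad_overlap_stats(loops, self.TADS)
        assert stats.n_within + stats.n_crossing == 1

    def test_overlapping_tads_rejected(self):
        bad = [GenomicInterval("c1", 0, 1_000), GenomicInterval("c1", 500, 2_000)]
        with pytest.raises(DataError, match="overlap"):
            tad_overlap_stats([], bad)


class TestLoopDistance:
    def test_midpoint_distance(self):
        lp = mk_loop("c1", 0, 10_000, 245_000, 255_000)
        assert loop_distance_stats([lp])["median"] == 245_000

    def test_lower_median_for_even_counts(self):
        loops = [mk_loop("c1", 0, 10, 0 + d, 10 + d) for d in (100, 200, 300, 400)]
        assert loop_distance_stats(loops)["median"] == 200

    def test_order_invariance_and_oracle(self):
        rng = np.random.default_rng(1)
        dists = [int(rng.integers(1_000, 1_000_000)) for _ in range(101)]
        loops = [mk_loop("c1", 0, 10, d, d + 10) for d in dists]
        stats = loop_distance_stats(loops)
        assert stats["median"] == bf_lower_median(dists)
        shuffled = [loops[i] for i in rng.permutation(len(loops))]
        assert loop_distance_stats(shuffled) == stats

    def test_no_intra_loops_is_an_error(self):
        inter = Loop(GenomicInterval("c1", 0, 10), GenomicInterval("c2", 0, 10))
        with pytest.raises(DataError):
            loop_distance_stats([inter])


class TestInteractionsPerGene:
    def test_mean_over_genes(self):
        tss = [make_tss("A", "c1", 100_000), make_tss("B", "c1", 500_000)]
        loops = [mk_loop("c1", 98_000, 103_000, 300_000, 305_000) for _ in range(3)]
        loops += [mk_loop("c1", 498_000, 503_000, 700_000, 705_000)]
        assert interactions_per_gene(loops, tss, {"A", "B"}) == 2.0

    def test_zero_count_genes_included(self):
        tss = [make_tss("A", "c1", 100_000), make_tss("B", "c1", 900_000)]
        loops = [mk_loop("c1", 98_000, 103_000, 300_000, 305_000)]
        assert interactions_per_gene(loops, tss, {"A", "B"}) == 0.5

    def test_empty_gene_set_rejected(self):
        with pytest.raises(DataError):
            interactions_per_gene([], [], set())

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            _, loops, tss, _ = random_instance(rng)
            genes = {r.gene_id for r in tss}
            got = interactions_per_gene(loops, tss, genes, window=5_000)
            assert got == pytest.approx(bf_interactions_per_gene(loops, tss, genes, 5_000))


class TestSnpPeakEnrichment:
    PEAKS = [Peak(GenomicInterval("c1", i * 10_000, i * 10_000 + 1_000)) for i in range(50)]

    @staticmethod
    def variants(positions):
        return [Variant(f"v{i}", "c1", p, 1.0, f"v{i}") for i, p in enumerate(positions)]

    def test_degenerate_all_in_peaks_background_never(self):
        snps = self.variants([100, 10_100, 20_100])
        background = self.variants([5_000 + i * 10_000 for i in range(100)])
        res = snp_peak_enrichment(snps, self.PEAKS, background, n_perm=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)
        assert res.degenerate and math.isinf(res.fold)

    def test_null_snps_give_fold_near_one(self):
        rng = np.random.default_rng(3)
        background = self.variants(list(rng.integers(0, 500_000, size=400)))
        snps = background[:50]
        res = snp_peak_enrichment(snps, self.PEAKS, background, n_perm=500, seed=1)
        assert 0.5 < res.fold < 2.0
        assert res.p_value > 0.01

    def test_bit_identical_for_same_seed(self):
        rng = np.random.default_rng(4)
        background = self.variants(list(rng.integers(0, 500_000, size=300)))
        snps = self.variants([100, 10_050, 30_100, 40_500])
        a = snp_peak_enrichment(snps, self.PEAKS, background, n_perm=300, seed=9)
        b = snp_peak_enrichment(snps, self.PEAKS, background, n_perm=300, seed=9)
        assert a == b

    def test_background_smaller_than_snps_rejected(self):
        snps = self.variants([1, 2, 3])
        with pytest.raises(DataError):
            snp_peak_enrichment(snps, self.PEAKS, snps[:2], n_perm=100, seed=0)


class TestLoopSetConcordance:
    def test_identical_sets(self):
        rng = np.random.default_rng(5)
        _, loops, _, _ = random_instance(rng)
        assert loop_set_concordance(loops, loops)["jaccard"] == 1.0

    def test_disjoint_sets(self):
        a = [mk_loop("c1", 0, 5_000, 100_000, 105_000)]
        b = [mk_loop("c1", 50_000, 55_000, 300_000, 305_000)]
        res = loop_set_concordance(a, b)
        assert res["jaccard"] == 0.0
        assert res["a_only"] == 1 and res["b_only"] == 1

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(6)
        for slack in (0, 5_000):
            for _ in range(10):
                _, la, _, _ = random_instance(rng, n_loops=40)
                _, lb, _, _ = random_instance(rng, n_loops=40)
                got = loop_set_concordance(la, lb, slack=slack)
                assert got == bf_loop_set_concordance(la, lb, slack, 5_000)
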