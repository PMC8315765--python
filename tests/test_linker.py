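import numpy as np
import pandas as pd
import pytest

from loopgene.annotate import ExpressionTable
from loopgene.core_io import ConfigurationError, GenomicInterval, Loop, Peak
from loopgene.linker import (
    LinkConfig,
    assemble_links,
    closest_gene_report,
    closest_genes_of_locus,
    disease_gene_counts,
    gene_desert_loci,
    genes_per_locus,
    link_by_loop,
    link_by_promoter,
)
from conftest import make_locus, make_tss, random_instance
from _oracles import (
    bf_closest_genes,
    bf_gene_desert,
    bf_link_by_loop,
    bf_link_by_promoter,
)


def expr_table(genes, tpm=10.0, samples=("s0", "s1")):
    frame = pd.DataFrame({s: [tpm] * len(genes) for s in samples}, index=list(genes))
    frame.index.name = "gene_id"
    return ExpressionTable(frame)


def loop_link_keys(links):
    return {
        (l.locus_id, l.gene_id, l.sample_id,
         (l.loop.anchor1.chrom, l.loop.anchor1.start, l.loop.anchor1.end,
          l.loop.anchor2.chrom, l.loop.anchor2.start, l.loop.anchor2.end))
        for l in links
    }


class TestLinkByLoop:
    def setup_method(self):
        self.loop = Loop(
            GenomicInterval("c1", 10_000, 15_000),
            GenomicInterval("c1", 200_000, 205_000),
            sample_id="s0",
        )
        self.locus = make_locus("rs1", "c1", [10_500])

    def test_snp_in_anchor_tss_inside_other_anchor(self):
        tss = [make_tss("G1", "c1", 204_000)]
        (link,) = link_by_loop([self.locus], [self.loop], tss)
        assert link.gene_id == "G1" and link.evidence == "loop"
        assert link.distance_bp == 0

    def test_window_boundary_is_inclusive(self):
        # TSS at 210,000: distance 210000 - 205000 + 1 = 5001 > 5000
        out = link_by_loop([self.locus], [self.loop], [make_tss("G1", "c1", 210_000)])
        assert out == []
        # one base closer: distance exactly 5000, linked
        (link,) = link_by_loop([self.locus], [self.loop], [make_tss("G1", "c1", 209_999)])
        assert link.distance_bp == 5_000

    def test_snp_outside_anchor_not_linked(self):
        locus = make_locus("rs2", "c1", [9_999])
        assert link_by_loop([locus], [self.loop], [make_tss("G1", "c1", 204_000)]) == []

    def test_snp_inside_both_anchors_links_both_directions(self):
        loop = Loop(
            GenomicInterval("c1", 10_000, 15_000),
            GenomicInterval("c1", 12_000, 17_000),
            sample_id="s0",
        )
        locus = make_locus("rs3", "c1", [12_500])
        tss = [make_tss("G1", "c1", 10_100), make_tss("G2", "c1", 16_900)]
        links = link_by_loop([locus], [loop], tss)
        assert {l.gene_id for l in links} == {"G1", "G2"}

    def test_empty_tss_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            link_by_loop([self.locus], [self.loop], [])

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            loci, loops, tss, _ = random_instance(rng)
            got = loop_link_keys(link_by_loop(loci, loops, tss))
            assert got == bf_link_by_loop(loci, loops, tss, loop_window=5_000)

    def test_enlarging_window_never_removes_links(self):
        rng = np.random.default_rng(8)
        loci, loops, tss, _ = random_instance(rng)
        prev = set()
        for w in (0, 1_000, 5_000, 20_000):
            cur = loop_link_keys(link_by_loop(loci, loops, tss, LinkConfig(loop_window=w)))
            assert prev <= cur
            prev = cur


class TestLinkByPromoter:
    def test_snp_in_peak_with_nearby_tss(self):
        locus = make_locus("rs1", "c1", [1_000])
        peaks = [Peak(GenomicInterval("c1", 900, 1_100), sample_id="s0")]
        (link,) = link_by_promoter([locus], peaks, [make_tss("G1", "c1", 1_500)])
        assert link.evidence == "promoter" and link.distance_bp == 500

    def test_peak_condition_is_mandatory(self):
        locus = make_locus("rs1", "c1", [1_000])
        out = link_by_promoter([locus], [], [make_tss("G1", "c1", 1_000)])
        assert out == []

    def test_window_boundary_inclusive(self):
        locus = make_locus("rs1", "c1", [1_000])
        peaks = [Peak(GenomicInterval("c1", 900, 1_100), sample_id="s0")]
        assert link_by_promoter([locus], peaks, [make_tss("G1", "c1", 2_000)])
        assert not link_by_promoter([locus], peaks, [make_tss("G1", "c1", 2_001)])

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            loci, _, tss, peaks = random_instance(rng)
            got = {(l.locus_id, l.gene_id, l.sample_id)
                   for l in link_by_promoter(loci, peaks, tss)}
            assert got == bf_link_by_promoter(loci, peaks, tss, promoter_window=1_000)


class TestAssembleLinks:
    def test_transcripts_collapse_to_one_gene_row(self):
        loop = Loop(GenomicInterval("c1", 10_000, 15_000),
                    GenomicInterval("c1", 200_000, 205_000), sample_id="s0")
        locus = make_locus("rs1", "c1", [10_500])
        tss = [make_tss("G1", "c1", 204_000, transcript="G1.t1"),
               make_tss("G1", "c1", 204_500, transcript="G1.t2")]
        links = link_by_loop([locus], [loop], tss)
        table = assemble_links(links, [], expr_table(["G1"]))
        assert len(table.frame) == 1
        assert table.frame.iloc[0]["expressed"] == 1

    def test_low_tpm_gene_excluded_from_reported_set_but_kept_in_table(self):
        loop = Loop(GenomicInterval("c1", 10_000, 15_000),
                    GenomicInterval("c1", 200_000, 205_000), sample_id="s0")
        locus = make_locus("rs1", "c1", [10_500])
        links = link_by_loop([locus], [loop], [make_tss("G1", "c1", 204_000)])
        table = assemble_links(links, [], expr_table(["G1"], tpm=0.5))
        assert len(table.frame) == 1
        assert table.gene_sets_by_locus() == {}
        assert table.gene_sets_by_locus(expressed_only=False) == {"rs1": {"G1"}}

    def test_gene_set_invariant_to_input_order_and_duplicates(self):
        rng = np.random.default_rng(10)
        loci, loops, tss, peaks = random_instance(rng)
        expr = expr_table({r.gene_id for r in tss})
        ll = link_by_loop(loci, loops, tss)
        pl = link_by_promoter(loci, peaks, tss)
        base = assemble_links(ll, pl, expr).gene_sets_by_locus()
        perm = assemble_links(list(reversed(ll)), list(reversed(pl)), expr)
        assert perm.gene_sets_by_locus() == base
        dup = assemble_links(ll + ll, pl, expr)
        assert dup.gene_sets_by_locus() == base

    def test_distance_respects_window_bound_on_random_runs(self):
        rng = np.random.default_rng(11)
        cfg = LinkConfig()
        for _ in range(5):
            loci, loops, tss, peaks = random_instance(rng)
            expr = expr_table({r.gene_id for r in tss})
            table = assemble_links(
                link_by_loop(loci, loops, tss, cfg),
                link_by_promoter(loci, peaks, tss, cfg),
                expr, cfg,
            )
            loop_rows = table.frame[table.frame["evidence"] == "loop"]
            prom_rows = table.frame[table.frame["evidence"] == "promoter"]
            assert (loop_rows["distance_bp"] <= cfg.loop_window).all()
            assert (prom_rows["distance_bp"] <= cfg.promoter_window).all()


class TestLocusSummaries:
    def _table(self, sets):
        rows = []
        for locus, genes in sets.items():
            for g in genes:
                rows.append({"locus_id": locus, "gene_id": g, "expressed": 1,
                             "sample_id": "s0", "evidence": "loop"})
        from loopgene.linker import LinkTable
        return LinkTable(pd.DataFrame(rows, columns=[
            "locus_id", "gene_id", "expressed", "sample_id", "evidence"]))

    def test_genes_per_locus_counts_and_means(self):
        table = self._table({"L1": {"A", "B"}, "L2": {"C"}})
        counts, mean_nz, mean_all = genes_per_locus(table)
        assert counts == {"L1": 2, "L2": 1}
        assert mean_nz == mean_all == 1.5

    def test_zero_gene_locus_enters_all_loci_mean_only(self):
        table = self._table({"L1": {"A", "B"}, "L2": {"C"}})
        counts, mean_nz, mean_all = genes_per_locus(table, ["L1", "L2", "L3"])
        assert counts["L3"] == 0
        assert mean_nz == 1.5
        assert mean_all == pytest.approx(1.0)

    def test_closest_gene_classification(self):
        tss = [make_tss("A", "c1", 1_000), make_tss("B", "c1", 50_000)]
        locus = make_locus("L1", "c1", [1_200])
        assert closest_genes_of_locus(locus, tss) == {"A"}
        report = closest_gene_report([locus], tss, self._table({"L1": {"A"}}))
        assert report == {"L1": "all_closest_linked"}
        report = closest_gene_report([locus], tss, self._table({"L1": {"B"}}))
        assert report == {"L1": "no_closest_linked"}

    def test_closest_gene_ties_included_and_partial_linkage(self):
        tss = [make_tss("A", "c1", 1_000), make_tss("B", "c1", 1_400)]
        locus = make_locus("L1", "c1", [1_200])  # equidistant from A and B
        assert closest_genes_of_locus(locus, tss) == {"A", "B"}
        report = closest_gene_report([locus], tss, self._table({"L1": {"A"}}))
        assert report == {"L1": "some_closest_linked"}

    def test_closest_report_restricted_to_small_blocks(self):
        tss = [make_tss("A", "c1", 1_000)]
        wide = make_locus("L1", "c1", [1_000, 250_000])
        assert closest_gene_report([wide], tss, self._table({})) == {}

    def test_closest_matches_bruteforce(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            loci, _, tss, _ = random_instance(rng)
            for locus in loci:
                assert closest_genes_of_locus(locus, tss) == bf_closest_genes(locus, tss)

    def test_gene_desert_boundaries(self):
        cfg = LinkConfig()
        locus = make_locus("L1", "c1", [0, 999])  # block (0, 1000)
        far = [make_tss("A", "c1", 60_000)]       # distance 59,001
        assert gene_desert_loci([locus], far, cfg) == ["L1"]
        near = [make_tss("A", "c1", 50_999)]      # distance exactly 50,000
        assert gene_desert_loci([locus], near, cfg) == []

    def test_gene_desert_matches_bruteforce(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            loci, _, tss, _ = random_instance(rng, n_tss=5, span=5_000_000)
            got = gene_desert_loci(loci, tss, LinkConfig())
            assert got == bf_gene_desert(loci, tss, 50_000)

    def test_disease_counts_union_across_samples(self):
        table = self._table({"L1": {"A", "B"}, "L2": {"B", "C"}})
        loci = [make_locus("L1", "c1", [10], disease="ps"),
                make_locus("L2", "c1", [20], disease="ps")]
        assert disease_gene_counts(table, loci) == {"ps": 3}
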