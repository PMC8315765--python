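"""Brute-force reference implementations used as independent oracles.

Every function here is a direct transcription of the linking/statistic
definitions as exhaustive loops over all tuples, with no indexing tricks, so
the optimized implementations in loopgene can be checked against them on
random instances.
"""

from __future__ import annotations

from loopgene.core_io import GenomicInterval, Loop, Peak, point_interval_distance
from loopgene.annotate import TssRecord
from loopgene.loci import LocusSet


def bf_point_interval_distance(pos: int, iv: GenomicInterval) -> int:
    return min(abs(pos - base) for base in range(iv.start, iv.end))


def bf_link_by_loop(loci, loops, tss, loop_window, snp_anchor_window=0):
    """Set of (locus_id, gene_id, sample_id, loop anchors) via triple loop."""
    out = set()
    for locus in loci:
        for v in locus.variants:
            for lp in loops:
                for anchor, other in ((lp.anchor1, lp.anchor2), (lp.anchor2, lp.anchor1)):
                    if v.chrom != anchor.chrom:
                        continue
                    if point_interval_distance(v.pos, anchor) > snp_anchor_window:
                        continue
                    for rec in tss:
                        if rec.chrom != other.chrom:
                            continue
                        if point_interval_distance(rec.tss, other) <= loop_window:
                            key = (
                                locus.locus_id, rec.gene_id, lp.sample_id,
                                (lp.anchor1.chrom, lp.anchor1.start, lp.anchor1.end,
                                 lp.anchor2.chrom, lp.anchor2.start, lp.anchor2.end),
                            )
                            out.add(key)
    return out


def bf_link_by_promoter(loci, peaks, tss, promoter_window):
    """Set of (locus_id, gene_id, sample_id) via triple loop."""
    out = set()
    for locus in loci:
        for v in locus.variants:
            for pk in peaks:
                if v.chrom != pk.interval.chrom:
                    continue
                if point_interval_distance(v.pos, pk.interval) != 0:
                    continue
                for rec in tss:
                    if rec.chrom == v.chrom and abs(rec.tss - v.pos) <= promoter_window:
                        out.add((locus.locus_id, rec.gene_id, pk.sample_id))
    return out


def bf_closest_genes(locus: LocusSet, tss) -> set[str]:
    out = set()
    for v in locus.variants:
        dists = [
            (abs(rec.tss - v.pos), rec.gene_id)
            for rec in tss
            if rec.chrom == locus.chrom
        ]
        if not dists:
            continue
        dmin = min(d for d, _ in dists)
        out |= {g for d, g in dists if d == dmin}
    return out


def bf_gene_desert(loci, tss, window) -> list[str]:
    out = []
    for locus in loci:
        dists = [
            point_interval_distance(rec.tss, locus.block)
            for rec in tss
            if rec.chrom == locus.chrom
        ]
        if not dists or min(dists) > window:
            out.append(locus.locus_id)
    return out


def bf_interactions_per_gene(loops, tss, gene_set, window) -> float:
    total = 0
    genes = sorted(gene_set)
    for gene in genes:
        recs = [r for r in tss if r.gene_id == gene]
        n = 0
        for lp in loops:
            hit = False
            for rec in recs:
                for anchor in (lp.anchor1, lp.anchor2):
                    if anchor.chrom == rec.chrom and \
                            point_interval_distance(rec.tss, anchor) <= window:
                        hit = True
            if hit:
                n += 1
        total += n
    return total / len(genes)


def bf_loop_set_concordance(loops_a, loops_b, slack, bin_size):
    def key(lp):
        return (
            lp.anchor1.chrom, lp.anchor1.midpoint // bin_size,
            lp.anchor2.chrom, lp.anchor2.midpoint // bin_size,
        )

    tol = slack // bin_size

    def match(k1, k2):
        return (k1[0] == k2[0] and k1[2] == k2[2]
                and abs(k1[1] - k2[1]) <= tol and abs(k1[3] - k2[3]) <= tol)

    ka = {key(lp) for lp in loops_a}
    kb = {key(lp) for lp in loops_b}
    shared = sum(1 for k1 in ka if any(match(k1, k2) for k2 in kb))
    a_only = len(ka) - shared
    b_only = sum(1 for k2 in kb if not any(match(k1, k2) for k1 in ka))
    denom = shared + a_only + b_only
    return {
        "jaccard": shared / denom if denom else float("nan"),
        "shared": float(shared),
        "a_only": float(a_only),
        "b_only": float(b_only),
    }


def bf_lower_median(values):
    s = sorted(values)
    return s[(len(s) - 1) // 2]
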