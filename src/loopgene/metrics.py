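"""Dataset- and result-level statistics.

Covers the evaluation side of the pipeline: concordance of linked genes with
eQTL gene sets (recall, and the fraction of linked genes supported by eQTLs
— reported as precision, also printed under its colloquial label
"specificity"), the fraction of loops contained within TADs, loop distance
summaries, interactions per gene, GWAS-SNP-in-peak permutation enrichment,
and replicate loop-set concordance.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .annotate import TssRecord
from .core_io import (
    DataError,
    GenomicInterval,
    Loop,
    Peak,
    point_interval_distance,
)
from .loci import Variant

PathLike = Union[str, Path]


@dataclass(frozen=True)
class ValidationResult:
    """Concordance of pipeline-linked genes with an eQTL gene set."""

    n_eqtl_genes: int
    n_linked_genes: int
    n_intersection: int
    recall: float
    precision: float

    def __post_init__(self) -> None:
        assert self.n_intersection <= min(self.n_eqtl_genes, self.n_linked_genes)


@dataclass(frozen=True)
class TadStats:
    n_within: int
    n_crossing: int
    fraction_within: float


@dataclass(frozen=True)
class EnrichmentResult:
    observed_fraction: float
    null_mean_fraction: float
    fold: float
    p_value: float
    n_perm: int
    degenerate: bool = False  # null mean was zero; fold reported as inf


def eqtl_validation(
    linked_genes: Mapping[str, Iterable[str]],
    eqtl_genes: Mapping[str, Iterable[str]],
    per_locus: bool = True,
) -> ValidationResult:
    """Recall and precision of linked genes against eQTL-implicated genes.

    Default matches per locus: counts are pooled over the union of loci, a
    gene matching only when both sides implicate it at the same locus. With
    ``per_locus=False`` both sides are collapsed to global gene unions first.
    Loci present on one side only contribute to that side's denominator.
    """
    if not eqtl_genes:
        raise DataError("empty eQTL mapping: recall undefined")
    linked = {k: set(v) for k, v in linked_genes.items()}
    eqtl = {k: set(v) for k, v in eqtl_genes.items()}
    if per_locus:
        loci = set(linked) | set(eqtl)
        n_eqtl = sum(len(eqtl.get(l, set())) for l in loci)
        n_linked = sum(len(linked.get(l, set())) for l in loci)
        n_inter = sum(len(eqtl.get(l, set()) & linked.get(l, set())) for l in loci)
    else:
        eqtl_u = set().union(*eqtl.values()) if eqtl else set()
        linked_u = set().union(*linked.values()) if linked else set()
        n_eqtl, n_linked = len(eqtl_u), len(linked_u)
        n_inter = len(eqtl_u & linked_u)
    recall = n_inter / n_eqtl if n_eqtl else float("nan")
    precision = n_inter / n_linked if n_linked else float("nan")
    return ValidationResult(n_eqtl, n_linked, n_inter, recall, precision)


def _validate_tads(tads: Sequence[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for t in tads:
        by_chrom[t.chrom].append(t)
    for chrom, ts in by_chrom.items():
        ts.sort(key=lambda t: t.start)
        for a, b in zip(ts, ts[1:]):
            if b.start < a.end:
                raise DataError(f"overlapping TADs on {chrom}: {a} / {b}")
    return dict(by_chrom)


def tad_overlap_stats(
    loops: Sequence[Loop], tads: Sequence[GenomicInterval]
) -> TadStats:
    """Count intra-chromosomal loops fully contained in a single TAD vs
    crossing a boundary. A loop is 'within' iff some one TAD contains both
    anchors entirely."""
    by_chrom = _validate_tads(tads)
    n_within = n_crossing = 0
    starts = {c: np.array([t.start for t in ts]) for c, ts in by_chrom.items()}
    for lp in loops:
        if not lp.intra_chromosomal:
            continue
        chrom = lp.anchor1.chrom
        within = False
        if chrom in by_chrom:
            # candidate TAD: last one starting at or before anchor1.start
            i = int(np.searchsorted(starts[chrom], lp.anchor1.start, side="right")) - 1
            if i >= 0:
                t = by_chrom[chrom][i]
                within = t.start <= lp.anchor1.start and lp.anchor2.end <= t.end
        if within:
            n_within += 1
        else:
            n_crossing += 1
    total = n_within + n_crossing
    frac = n_within / total if total else float("nan")
    return TadStats(n_within, n_crossing, frac)


def loop_distance_stats(loops: Sequence[Loop]) -> dict[str, float]:
    """Median (lower median for even counts), mean and quartiles of the
    anchor-midpoint distance over intra-chromosomal loops."""
    dists = np.sort(
        np.array([lp.distance for lp in loops if lp.intra_chromosomal], dtype=np.int64)
    )
    if dists.size == 0:
        raise DataError("no intra-chromosomal loops: distance stats undefined")
    n = dists.size
    return {
        "n": float(n),
        "median": float(dists[(n - 1) // 2]),
        "mean": float(dists.mean()),
        "q25": float(np.quantile(dists, 0.25)),
        "q75": float(np.quantile(dists, 0.75)),
    }


def interactions_per_gene(
    loops: Sequence[Loop],
    tss: Sequence[TssRecord],
    gene_set: Iterable[str],
    window: int = 5_000,
) -> float:
    """Mean number of loops per gene with at least one anchor within
    ``window`` bp of any TSS of the gene; genes with zero loops included."""
    genes = set(gene_set)
    if not genes:
        raise DataError("empty gene set")
    tss_by_gene: dict[str, list[TssRecord]] = defaultdict(list)
    for rec in tss:
        if rec.gene_id in genes:
            tss_by_gene[rec.gene_id].append(rec)
    counts = []
    for gene in sorted(genes):
        recs = tss_by_gene.get(gene, [])
        n = 0
        for lp in loops:
            hit = any(
                anchor.chrom == rec.chrom
                and point_interval_distance(rec.tss, anchor) <= window
                for rec in recs
                for anchor in (lp.anchor1, lp.anchor2)
            )
            if hit:
                n += 1  # each loop counted once per gene
        counts.append(n)
    return float(np.mean(counts))


def snp_peak_enrichment(
    snps: Sequence[Variant],
    peaks: Sequence[Peak],
    background_snps: Sequence[Variant],
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation enrichment of SNPs in peaks against a background pool.

    Observed statistic: fraction of ``snps`` inside any peak. Null: draw
    ``len(snps)`` variants from the background without replacement and
    recompute; repeated ``n_perm`` times. The p-value uses the add-one
    estimator (1 + #{null >= observed}) / (n_perm + 1) so it can never be
    exactly zero. Bit-identical across runs for a fixed seed.
    """
    if len(background_snps) < len(snps):
        raise DataError("background pool smaller than the SNP set")
    if n_perm < 100:
        raise DataError("n_perm must be >= 100")
    peak_by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for pk in peaks:
        peak_by_chrom[pk.interval.chrom].append((pk.interval.start, pk.interval.end))
    # overlapping peaks are unioned: membership only needs the merged cover
    merged = {}
    for chrom, ivs in peak_by_chrom.items():
        ivs.sort()
        spans: list[list[int]] = []
        for s, e in ivs:
            if spans and s <= spans[-1][1]:
                spans[-1][1] = max(spans[-1][1], e)
            else:
                spans.append([s, e])
        merged[chrom] = (
            np.array([s for s, _ in spans]),
            np.array([e for _, e in spans]),
        )

    def in_peak(vs: Sequence[Variant]) -> np.ndarray:
        out = np.zeros(len(vs), dtype=bool)
        for i, v in enumerate(vs):
            if v.chrom not in merged:
                continue
            starts, ends = merged[v.chrom]
            j = int(np.searchsorted(starts, v.pos, side="right")) - 1
            out[i] = j >= 0 and v.pos < ends[j]
        return out

    observed = float(in_peak(snps).mean()) if snps else 0.0
    bg_flags = in_peak(background_snps).astype(float)
    rng = np.random.default_rng(seed)
    k = len(snps)
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(len(bg_flags), size=k, replace=False)
        null[i] = bg_flags[idx].mean()
    null_mean = float(null.mean())
    p = (1 + int((null >= observed - 1e-12).sum())) / (n_perm + 1)
    if null_mean == 0.0:
        fold = math.inf if observed > 0 else float("nan")
        return EnrichmentResult(observed, null_mean, fold, p, n_perm, degenerate=True)
    return EnrichmentResult(observed, null_mean, observed / null_mean, p, n_perm)


def loop_set_concordance(
    loops_a: Sequence[Loop],
    loops_b: Sequence[Loop],
    slack: int = 0,
    bin_size: int = 5_000,
) -> dict[str, float]:
    """Replicate concordance: loops match when both anchor midpoints fall in
    the same ``bin_size`` grid bin (within ``slack`` bp of grid tolerance).

    Returns the Jaccard index over binned loop keys plus shared/only counts.
    """
    if slack < 0:
        raise ValueError("slack must be >= 0")
    tol = slack // bin_size  # allowed bin-index offset per anchor

    def keys(loops: Sequence[Loop]) -> set[tuple]:
        return {
            (
                lp.anchor1.chrom,
                lp.anchor1.midpoint // bin_size,
                lp.anchor2.chrom,
                lp.anchor2.midpoint // bin_size,
            )
            for lp in loops
        }

    ka, kb = keys(loops_a), keys(loops_b)
    if tol == 0:
        shared = len(ka & kb)
        a_only = len(ka - kb)
        b_only = len(kb - ka)
    else:
        def matches(k1: tuple, k2: tuple) -> bool:
            return (
                k1[0] == k2[0]
                and k1[2] == k2[2]
                and abs(k1[1] - k2[1]) <= tol
                and abs(k1[3] - k2[3]) <= tol
            )

        shared = sum(1 for k1 in ka if any(matches(k1, k2) for k2 in kb))
        a_only = len(ka) - shared
        b_only = sum(1 for k2 in kb if not any(matches(k1, k2) for k1 in ka))
    denom = shared + a_only + b_only
    jaccard = shared / denom if denom else float("nan")
    return {
        "jaccard": jaccard,
        "shared": float(shared),
        "a_only": float(a_only),
        "b_only": float(b_only),
    }


def read_eqtl_sets(path: PathLike) -> dict[str, set[str]]:
    """Read an eQTL TSV (locus_id, gene_id) into per-locus gene sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"locus_id", "gene_id"} <= set(df.columns):
        raise DataError(f"{path}: expected columns locus_id, gene_id")
    out: dict[str, set[str]] = defaultdict(set)
    for row in df.itertuples():
        out[row.locus_id].add(row.gene_id)
    return dict(out)
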