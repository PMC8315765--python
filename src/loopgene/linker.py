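"""Assign candidate target genes to GWAS loci.

Two evidence routes, mirroring how anchor-resolution H3K27ac HiChIP loops are
used for SNP-to-gene assignment:

* **loop**: a variant of the locus falls inside one anchor of a significant
  loop and a transcript's TSS lies within ``loop_window`` (default 5 kb) of
  the other anchor;
* **promoter**: a variant overlaps an H3K27ac peak and a TSS lies within
  ``promoter_window`` (default 1 kb) of the variant itself.

Transcript-level hits are grouped to gene level and genes are then filtered
by expression (>= 1 TPM in the cell line that provided the evidence). Rows
failing the filter are retained with ``expressed = 0`` so the filter's effect
is auditable; reported gene sets use expressed rows only.
"""

from __future__ import annotations

import hashlib
import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotate import ExpressionTable, TssRecord, is_expressed
from .core_io import (
    ConfigurationError,
    GenomicInterval,
    Loop,
    Peak,
    point_interval_distance,
)
from .loci import LocusSet, Variant, block_width_class

logger = logging.getLogger(__name__)

LINK_COLUMNS = [
    "locus_id",
    "lead_snp",
    "snp_id",
    "snp_chrom",
    "snp_pos_1based",
    "gene_id",
    "gene_name",
    "evidence",
    "sample_id",
    "loop_anchor1",
    "loop_anchor2",
    "tss_pos_1based",
    "distance_bp",
    "expressed",
    "tpm",
]


@dataclass(frozen=True)
class LinkConfig:
    """Windows and thresholds of the linking rules (all in bp except TPM)."""

    loop_window: int = 5_000
    promoter_window: int = 1_000
    tpm_threshold: float = 1.0
    gene_desert_window: int = 50_000
    block_width_cutoff: int = 100_000
    snp_anchor_window: int = 0

    def __post_init__(self) -> None:
        for name in (
            "loop_window",
            "promoter_window",
            "gene_desert_window",
            "block_width_cutoff",
            "snp_anchor_window",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.tpm_threshold < 0:
            raise ConfigurationError("tpm_threshold must be >= 0")


@dataclass(frozen=True)
class GeneLink:
    locus_id: str
    lead_snp: str
    snp_id: str
    gene_id: str
    gene_name: str
    evidence: str  # "loop" | "promoter"
    sample_id: str
    tss: TssRecord
    distance_bp: int
    variant: Variant
    loop: Optional[Loop] = None
    expressed: Optional[bool] = None
    tpm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.evidence == "loop" and self.loop is None:
            raise ValueError("loop evidence requires a supporting loop")


def _loop_key(loop: Optional[Loop]) -> tuple:
    if loop is None:
        return ()
    a, b = loop.anchor1, loop.anchor2
    return (a.chrom, a.start, a.end, b.chrom, b.start, b.end)


def _anchor_trees(
    loops: Sequence[Loop], pad: int
) -> dict[str, IntervalTree]:
    """Per-chromosome stabbing index over loop anchors, expanded by ``pad``
    so a query at position p hits anchors with point_interval_distance <= pad."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for idx, lp in enumerate(loops):
        for which, anchor in ((1, lp.anchor1), (2, lp.anchor2)):
            trees[anchor.chrom].addi(anchor.start - pad, anchor.end + pad, (idx, which))
    return dict(trees)


def _tss_index(tss: Sequence[TssRecord]) -> dict[str, tuple[np.ndarray, list[TssRecord]]]:
    by_chrom: dict[str, list[TssRecord]] = defaultdict(list)
    for rec in tss:
        by_chrom[rec.chrom].append(rec)
    out = {}
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda r: (r.tss, r.transcript_id))
        out[chrom] = (np.array([r.tss for r in recs], dtype=np.int64), recs)
    return out


def _tss_in_range(
    index: Mapping[str, tuple[np.ndarray, list[TssRecord]]],
    chrom: str,
    lo: int,
    hi: int,
) -> list[TssRecord]:
    """TSS records with position in the half-open window [lo, hi)."""
    if chrom not in index:
        return []
    positions, recs = index[chrom]
    i = int(np.searchsorted(positions, lo, side="left"))
    j = int(np.searchsorted(positions, hi, side="left"))
    return recs[i:j]


def link_by_loop(
    loci: Sequence[LocusSet],
    loops: Sequence[Loop],
    tss: Sequence[TssRecord],
    cfg: LinkConfig = LinkConfig(),
) -> list[GeneLink]:
    """Loop-mediated links: variant inside one anchor, TSS within
    ``cfg.loop_window`` of the other anchor.

    If a variant sits inside both anchors both directions are evaluated.
    Hits are deduplicated to (locus, gene, loop, sample) level, keeping the
    smallest TSS-anchor distance.
    """
    if not tss:
        raise ConfigurationError("empty TSS list: load an annotation first")
    trees = _anchor_trees(loops, cfg.snp_anchor_window)
    tidx = _tss_index(tss)
    best: dict[tuple, GeneLink] = {}
    for locus in loci:
        lead = locus.locus_id
        for v in locus.variants:
            tree = trees.get(v.chrom)
            if tree is None:
                continue
            for hit in tree[v.pos]:
                idx, which = hit.data
                lp = loops[idx]
                other = lp.anchor2 if which == 1 else lp.anchor1
                lo = other.start - cfg.loop_window
                hi = other.end + cfg.loop_window  # [start-w, end+w) <=> dist <= w
                for rec in _tss_in_range(tidx, other.chrom, lo, hi):
                    dist = point_interval_distance(rec.tss, other)
                    key = (lead, rec.gene_id, lp.sample_id, _loop_key(lp))
                    prev = best.get(key)
                    if prev is None or dist < prev.distance_bp:
                        best[key] = GeneLink(
                            locus_id=lead,
                            lead_snp=lead,
                            snp_id=v.snp_id,
                            gene_id=rec.gene_id,
                            gene_name=rec.gene_name,
                            evidence="loop",
                            sample_id=lp.sample_id,
                            tss=rec,
                            distance_bp=dist,
                            variant=v,
                            loop=lp,
                        )
    return sorted(
        best.values(),
        key=lambda g: (g.locus_id, g.gene_id, g.sample_id, _loop_key(g.loop)),
    )


def link_by_promoter(
    loci: Sequence[LocusSet],
    peaks: Sequence[Peak],
    tss: Sequence[TssRecord],
    cfg: LinkConfig = LinkConfig(),
) -> list[GeneLink]:
    """Promoter-overlap links: variant inside an H3K27ac peak, TSS within
    ``cfg.promoter_window`` of the variant position."""
    if not tss:
        raise ConfigurationError("empty TSS list: load an annotation first")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for pk in peaks:
        iv = pk.interval
        trees[iv.chrom].addi(iv.start, iv.end, pk)
    tidx = _tss_index(tss)
    best: dict[tuple, GeneLink] = {}
    for locus in loci:
        lead = locus.locus_id
        for v in locus.variants:
            tree = trees.get(v.chrom)
            if tree is None:
                continue
            samples = {hit.data.sample_id for hit in tree[v.pos]}
            if not samples:
                continue
            lo = v.pos - cfg.promoter_window
            hi = v.pos + cfg.promoter_window + 1  # |tss - pos| <= w
            for rec in _tss_in_range(tidx, v.chrom, lo, hi):
                dist = abs(rec.tss - v.pos)
                for sample in samples:
                    key = (lead, rec.gene_id, sample)
                    prev = best.get(key)
                    if prev is None or dist < prev.distance_bp:
                        best[key] = GeneLink(
                            locus_id=lead,
                            lead_snp=lead,
                            snp_id=v.snp_id,
                            gene_id=rec.gene_id,
                            gene_name=rec.gene_name,
                            evidence="promoter",
                            sample_id=sample,
                            tss=rec,
                            distance_bp=dist,
                            variant=v,
                        )
    return sorted(best.values(), key=lambda g: (g.locus_id, g.gene_id, g.sample_id))


@dataclass
class LinkTable:
    """Gene-level link evidence rows plus run provenance."""

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def expressed_frame(self) -> pd.DataFrame:
        return self.frame[self.frame["expressed"] == 1]

    def gene_sets_by_locus(self, expressed_only: bool = True) -> dict[str, set[str]]:
        frame = self.expressed_frame() if expressed_only else self.frame
        out: dict[str, set[str]] = {}
        for locus_id, grp in frame.groupby("locus_id"):
            out[str(locus_id)] = set(grp["gene_id"])
        return out

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "LinkTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"locus_id": str, "snp_id": str}))

    def digest(self) -> str:
        payload = self.frame.to_csv(sep="\t", index=False, float_format="%.6g")
        return hashlib.sha256(payload.encode()).hexdigest()


def _fmt_interval(iv: Optional[GenomicInterval]) -> str:
    return "" if iv is None else f"{iv.chrom}:{iv.start}-{iv.end}"


def assemble_links(
    loop_links: Sequence[GeneLink],
    promoter_links: Sequence[GeneLink],
    expr: ExpressionTable,
    cfg: LinkConfig = LinkConfig(),
) -> LinkTable:
    """Merge evidence routes into the gene-level link table.

    Each row carries the expression status of the gene in the evidence row's
    sample; genes absent from the expression table count as not expressed
    (logged). Unexpressed rows are retained for audit but excluded from
    reported gene sets.
    """
    rows = []
    missing_expr = 0
    for link in list(loop_links) + list(promoter_links):
        tpm = expr.tpm(link.gene_id, link.sample_id)
        if tpm is None:
            missing_expr += 1
        expressed = is_expressed(link.gene_id, link.sample_id, expr, cfg.tpm_threshold)
        lp = link.loop
        rows.append(
            {
                "locus_id": link.locus_id,
                "lead_snp": link.lead_snp,
                "snp_id": link.snp_id,
                "snp_chrom": link.variant.chrom,
                "snp_pos_1based": link.variant.pos + 1,
                "gene_id": link.gene_id,
                "gene_name": link.gene_name,
                "evidence": link.evidence,
                "sample_id": link.sample_id,
                "loop_anchor1": _fmt_interval(lp.anchor1 if lp else None),
                "loop_anchor2": _fmt_interval(lp.anchor2 if lp else None),
                "tss_pos_1based": link.tss.tss + 1,
                "distance_bp": link.distance_bp,
                "expressed": int(expressed),
                "tpm": np.nan if tpm is None else tpm,
            }
        )
    if missing_expr:
        logger.warning(
            "%d link rows reference genes absent from the expression table "
            "(treated as not expressed)",
            missing_expr,
        )
    frame = pd.DataFrame(rows, columns=LINK_COLUMNS)
    frame = frame.drop_duplicates(
        subset=["locus_id", "gene_id", "evidence", "sample_id", "loop_anchor1", "loop_anchor2"]
    )
    frame = frame.sort_values(
        ["locus_id", "gene_id", "evidence", "sample_id", "loop_anchor1"],
        kind="mergesort",
    ).reset_index(drop=True)
    return LinkTable(frame, provenance={"config": cfg.__dict__.copy()})


def genes_per_locus(
    table: LinkTable,
    all_locus_ids: Optional[Iterable[str]] = None,
) -> tuple[dict[str, int], float, float]:
    """Unique expressed genes per locus.

    Returns (counts, mean over loci with >= 1 gene, mean over all loci).
    ``all_locus_ids`` supplies the locus universe so zero-gene loci enter the
    all-loci mean; defaults to the loci present in the table.
    """
    sets = table.gene_sets_by_locus(expressed_only=True)
    universe = set(all_locus_ids) if all_locus_ids is not None else set(sets)
    counts = {locus: len(sets.get(locus, set())) for locus in sorted(universe)}
    nonzero = [c for c in counts.values() if c > 0]
    mean_nonzero = float(np.mean(nonzero)) if nonzero else float("nan")
    mean_all = float(np.mean(list(counts.values()))) if counts else float("nan")
    return counts, mean_nonzero, mean_all


def closest_genes_of_locus(
    locus: LocusSet, tss: Sequence[TssRecord]
) -> set[str]:
    """Union over the locus's variants of the gene(s) whose TSS minimizes the
    distance to that variant; ties all included."""
    chrom_tss = [r for r in tss if r.chrom == locus.chrom]
    closest: set[str] = set()
    for v in locus.variants:
        dmin = None
        genes_at_min: set[str] = set()
        for rec in chrom_tss:
            d = abs(rec.tss - v.pos)
            if dmin is None or d < dmin:
                dmin = d
                genes_at_min = {rec.gene_id}
            elif d == dmin:
                genes_at_min.add(rec.gene_id)
        closest |= genes_at_min
    return closest


def closest_gene_report(
    loci: Sequence[LocusSet],
    tss: Sequence[TssRecord],
    table: LinkTable,
    cfg: LinkConfig = LinkConfig(),
) -> dict[str, str]:
    """Classify loci with LD block narrower than ``cfg.block_width_cutoff`` by
    whether their closest protein-coding gene(s) are among the linked
    expressed genes: all / some / none of the closest set linked."""
    linked = table.gene_sets_by_locus(expressed_only=True)
    out: dict[str, str] = {}
    for locus in loci:
        if block_width_class(locus, cfg.block_width_cutoff) != "small":
            continue
        closest = closest_genes_of_locus(locus, tss)
        if not closest:
            logger.warning("locus %s: no TSS on chromosome %s", locus.locus_id, locus.chrom)
            out[locus.locus_id] = "no_closest_linked"
            continue
        hit = closest & linked.get(locus.locus_id, set())
        if hit == closest:
            out[locus.locus_id] = "all_closest_linked"
        elif hit:
            out[locus.locus_id] = "some_closest_linked"
        else:
            out[locus.locus_id] = "no_closest_linked"
    return out


def gene_desert_loci(
    loci: Sequence[LocusSet],
    tss: Sequence[TssRecord],
    cfg: LinkConfig = LinkConfig(),
) -> list[str]:
    """Loci with no protein-coding TSS within ``cfg.gene_desert_window`` of
    the LD block."""
    tidx = _tss_index(list(tss))
    out = []
    for locus in loci:
        w = cfg.gene_desert_window
        near = _tss_in_range(
            tidx, locus.chrom, locus.block.start - w, locus.block.end + w
        )
        if not near:
            out.append(locus.locus_id)
    return out


def disease_gene_counts(
    table: LinkTable, loci: Sequence[LocusSet]
) -> dict[str, int]:
    """Unique expressed linked genes per disease, unioned across samples and
    loci (the headline per-disease count)."""
    disease_of = {locus.locus_id: locus.disease for locus in loci}
    genes: dict[str, set[str]] = defaultdict(set)
    for locus_id, gene_set in table.gene_sets_by_locus(expressed_only=True).items():
        genes[disease_of.get(locus_id, "")] |= gene_set
    return {d: len(g) for d, g in sorted(genes.items())}
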