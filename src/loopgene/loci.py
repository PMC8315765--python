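"""GWAS loci: lead SNPs, their LD proxies, and derived LD-block spans.

LD itself is precomputed upstream; the input table carries r2 of each proxy
against its lead. Input positions are 1-based (GWAS-catalog/VCF convention)
and converted to the internal 0-based convention on ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import pandas as pd

from .core_io import DataError, GenomicInterval, normalize_chrom

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

DEFAULT_R2_THRESHOLD = 0.8
DEFAULT_BLOCK_WIDTH_CUTOFF = 100_000


@dataclass(frozen=True)
class Variant:
    """A SNP with its LD (r2) to the lead SNP of its locus. pos is 0-based."""

    snp_id: str
    chrom: str
    pos: int
    r2: float
    locus_id: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"r2 {self.r2} outside [0, 1] for {self.snp_id}")
        if self.pos < 0:
            raise ValueError(f"negative position for {self.snp_id}")


@dataclass(frozen=True)
class LocusSet:
    """A lead SNP plus surviving proxies, with the spanned LD block."""

    locus_id: str
    variants: tuple[Variant, ...]
    block: GenomicInterval
    disease: str = ""

    @property
    def chrom(self) -> str:
        return self.block.chrom

    @property
    def width(self) -> int:
        return self.block.end - self.block.start


def build_loci(
    snp_table: PathLike,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    strict: bool = False,
) -> list[LocusSet]:
    """Group a SNP TSV (snp_id, chrom, pos_1based, locus_id, r2[, disease])
    into loci.

    Proxies with r2 >= threshold are kept (`strict=True` switches to >,
    matching the other reading of "r2 > 0.8"); the lead SNP (r2 = 1,
    snp_id == locus_id) always survives the default threshold. The LD block
    spans min..max surviving positions, half-open.
    """
    if not 0.0 <= r2_threshold <= 1.0:
        raise ValueError("r2_threshold outside [0, 1]")
    df = pd.read_csv(snp_table, sep="\t", dtype={"snp_id": str, "locus_id": str, "chrom": str})
    required = {"snp_id", "chrom", "pos_1based", "locus_id", "r2"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{snp_table}: missing columns {sorted(missing)}")
    if "disease" not in df.columns:
        df["disease"] = ""

    loci: list[LocusSet] = []
    for locus_id, grp in df.groupby("locus_id", sort=True):
        chroms = {normalize_chrom(c) for c in grp["chrom"]}
        if len(chroms) > 1:
            raise DataError(
                f"locus {locus_id}: variants on multiple chromosomes {sorted(chroms)}"
            )
        if grp["snp_id"].duplicated().any():
            dupes = grp.loc[grp["snp_id"].duplicated(), "snp_id"].tolist()
            logger.warning("locus %s: deduplicating snp_ids %s", locus_id, dupes)
            grp = grp.drop_duplicates(subset="snp_id")
        keep = grp["r2"] > r2_threshold if strict else grp["r2"] >= r2_threshold
        grp = grp[keep]
        if grp.empty:
            logger.warning("locus %s: no variants at r2 threshold %s", locus_id, r2_threshold)
            continue
        variants = tuple(
            sorted(
                (
                    Variant(
                        snp_id=row.snp_id,
                        chrom=normalize_chrom(row.chrom),
                        pos=int(row.pos_1based) - 1,
                        r2=float(row.r2),
                        locus_id=str(locus_id),
                    )
                    for row in grp.itertuples()
                ),
                key=lambda v: (v.pos, v.snp_id),
            )
        )
        positions = [v.pos for v in variants]
        block = GenomicInterval(variants[0].chrom, min(positions), max(positions) + 1)
        disease = str(grp["disease"].iloc[0])
        loci.append(LocusSet(str(locus_id), variants, block, disease))
    return loci


def block_width_class(
    locus: LocusSet, width_cutoff: int = DEFAULT_BLOCK_WIDTH_CUTOFF
) -> str:
    """'small' iff the LD block is strictly narrower than the cutoff."""
    if width_cutoff <= 0:
        raise ValueError("width_cutoff must be positive")
    return "small" if locus.width < width_cutoff else "large"
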