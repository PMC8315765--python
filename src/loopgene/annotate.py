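"""Transcription start sites from a GTF and the expressed-gene (TPM) filter.

The linking rules operate on the TSS of every protein-coding transcript;
candidate genes are then kept only when expressed at >= 1 TPM in the cell
line that provided the loop or peak evidence.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from gffutils.feature import feature_from_line

from .core_io import ConfigurationError, ParseError, normalize_chrom

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

DEFAULT_BIOTYPES = frozenset({"protein_coding"})

# Gencode writes gene_type/transcript_type, Ensembl writes *_biotype
_BIOTYPE_KEYS = ("gene_type", "gene_biotype", "transcript_type", "transcript_biotype")


@dataclass(frozen=True)
class TssRecord:
    """One transcript's start site (0-based) with its gene identity."""

    gene_id: str
    gene_name: str
    transcript_id: str
    chrom: str
    tss: int
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("negative TSS coordinate")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")


def extract_tss(
    annotation: PathLike,
    biotypes: Optional[Iterable[str]] = None,
) -> list[TssRecord]:
    """One TSS record per transcript of the requested biotypes.

    The GTF is 1-based inclusive; the TSS is the 5' end of the transcript
    (start for + strand, end for - strand) converted to a 0-based coordinate.
    Transcripts with strand '.' are skipped with a logged count. Duplicate
    transcript_ids raise, since downstream grouping assumes uniqueness.
    """
    wanted = frozenset(biotypes) if biotypes is not None else DEFAULT_BIOTYPES
    path = Path(annotation)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[TssRecord] = []
    seen: set[str] = set()
    skipped_strand = 0
    with opener(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "transcript":
                continue
            feat = feature_from_line(raw)
            biotype = None
            for key in _BIOTYPE_KEYS:
                if key in feat.attributes:
                    biotype = feat.attributes[key][0]
                    break
            if biotype is None or biotype not in wanted:
                continue
            if feat.strand == ".":
                skipped_strand += 1
                continue
            try:
                gene_id = feat.attributes["gene_id"][0]
                transcript_id = feat.attributes["transcript_id"][0]
            except KeyError as exc:
                raise ParseError(
                    f"{path}:{lineno}: transcript feature missing {exc} attribute"
                ) from exc
            gene_name = feat.attributes.get("gene_name", [gene_id])[0]
            if transcript_id in seen:
                raise ParseError(
                    f"{path}:{lineno}: duplicate transcript_id {transcript_id}"
                )
            seen.add(transcript_id)
            # GTF is 1-based inclusive: 5' end -> 0-based is start-1 (+) / end-1 (-)
            tss = feat.start - 1 if feat.strand == "+" else feat.end - 1
            records.append(
                TssRecord(
                    gene_id=gene_id,
                    gene_name=gene_name,
                    transcript_id=transcript_id,
                    chrom=normalize_chrom(feat.seqid),
                    tss=tss,
                    strand=feat.strand,
                    biotype=biotype,
                )
            )
    if skipped_strand:
        logger.warning("skipped %d transcripts with strand '.'", skipped_strand)
    records.sort(key=lambda r: (r.chrom, r.tss, r.transcript_id))
    return records


class ExpressionTable:
    """gene_id x sample_id TPM matrix backed by a DataFrame."""

    def __init__(self, frame: pd.DataFrame):
        if (frame.values < 0).any():
            raise ValueError("negative TPM values")
        self._frame = frame

    @classmethod
    def from_tsv(cls, path: PathLike) -> "ExpressionTable":
        """Read a TSV with a ``gene_id`` column and one TPM column per sample."""
        frame = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(frame.astype(float))

    def to_tsv(self, path: PathLike) -> None:
        self._frame.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")

    @property
    def samples(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def genes(self) -> list[str]:
        return list(self._frame.index)

    def tpm(self, gene_id: str, sample_id: str) -> Optional[float]:
        """TPM, or None if the gene was not measured."""
        if sample_id not in self._frame.columns:
            raise ConfigurationError(
                f"unknown sample {sample_id!r}; known samples: {self.samples}"
            )
        if gene_id not in self._frame.index:
            return None
        return float(self._frame.at[gene_id, sample_id])


def is_expressed(
    gene_id: str,
    sample_id: str,
    table: ExpressionTable,
    threshold: float = 1.0,
) -> bool:
    """True iff the gene was measured at TPM >= threshold in the sample.

    Genes absent from the table count as not expressed (conservative: the
    filter acts on measured TPM only).
    """
    if threshold < 0:
        raise ConfigurationError("TPM threshold must be >= 0")
    tpm = table.tpm(gene_id, sample_id)
    return tpm is not None and tpm >= threshold
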