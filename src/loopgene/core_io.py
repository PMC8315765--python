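"""Genomic interval primitives and readers/writers for BED, BEDPE and narrowPeak.

All internal coordinates are 0-based half-open (BED convention). SNP/GWAS
positions arrive 1-based and are converted on ingest by the callers in
:mod:`loopgene.loci`. Chromosome names are normalized so that ``"1"`` and
``"chr1"`` address the same sequence; mitochondrial and haplotype contigs are
passed through verbatim.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, TextIO, Union

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A malformed line in a genomic text format; message names the line."""


class ConfigurationError(ValueError):
    """An invalid parameter combination (bad column index, unknown sample...)."""


class DataError(ValueError):
    """Structurally valid input that violates a data contract."""


_MAIN_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y"}


def normalize_chrom(name: str) -> str:
    """Map ``chr1``/``1`` style names onto a single key (the bare form).

    Only the ordinary autosomes and X/Y are stripped of a ``chr`` prefix;
    mitochondrial and haplotype/scaffold contigs are returned verbatim so the
    two mitochondrial dialects ("chrM", "MT") stay distinct rather than being
    guessed at. Idempotent.
    """
    if not name:
        raise ValueError("empty chromosome name")
    if name.startswith("chr") and name[3:] in _MAIN_CHROMS:
        return name[3:]
    return name


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a (normalized) chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Loop:
    """A significant chromatin interaction between two anchor intervals.

    Anchors are stored in sorted genomic order when on the same chromosome.
    Inter-chromosomal loops are representable but excluded from distance and
    TAD statistics by the consumers.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    score: Optional[float] = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        a, b = self.anchor1, self.anchor2
        if (a.chrom, a.start, a.end) > (b.chrom, b.start, b.end):
            object.__setattr__(self, "anchor1", b)
            object.__setattr__(self, "anchor2", a)

    @property
    def intra_chromosomal(self) -> bool:
        return self.anchor1.chrom == self.anchor2.chrom

    @property
    def distance(self) -> int:
        """Anchor-midpoint separation in bp (intra-chromosomal loops only)."""
        if not self.intra_chromosomal:
            raise ValueError("distance undefined for inter-chromosomal loop")
        return abs(self.anchor2.midpoint - self.anchor1.midpoint)


@dataclass(frozen=True)
class Peak:
    """An H3K27ac (or other) ChIP peak with optional signal value."""

    interval: GenomicInterval
    signal: Optional[float] = None
    sample_id: str = ""


def point_interval_distance(pos: int, iv: GenomicInterval) -> int:
    """Distance in bp from a base position to a half-open interval.

    0 when the position lies inside the interval; otherwise the number of
    bases separating ``pos`` from the nearest base of the interval (the last
    base of [start, end) being end - 1).
    """
    if pos < 0:
        raise ValueError("negative position")
    if pos < iv.start:
        return iv.start - pos
    if pos >= iv.end:
        return pos - iv.end + 1
    return 0


def interval_interval_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Gap in bp between two intervals on the same chromosome; 0 if they touch
    or overlap."""
    if a.chrom != b.chrom:
        raise ValueError("intervals on different chromosomes")
    if a.start >= b.end:
        return a.start - b.end + 1
    if b.start >= a.end:
        return b.start - a.end + 1
    return 0


# ---------------------------------------------------------------------------
# readers / writers


def _open_text(path: PathLike) -> TextIO:
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, "rt")
    return open(p)


def _data_lines(handle: TextIO) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) skipping comments and track lines."""
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        yield lineno, line.split("\t")


def read_bed(path: PathLike) -> list[GenomicInterval]:
    """Read a BED3+ file into intervals (0-based half-open, per the standard)."""
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(path: PathLike, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def read_bedpe_loops(
    path: PathLike,
    score_column: Optional[int] = None,
    score_threshold: Optional[float] = None,
    sample_id: str = "",
) -> list[Loop]:
    """Read loops from a BEDPE-like file (FitHiChIP significant interactions).

    Only the first six columns (chrom1, start1, end1, chrom2, start2, end2)
    are required. ``score_column`` is a 0-based column index; when given, the
    score is populated and, if ``score_threshold`` is also given, rows with
    score > threshold are dropped (the column is read as a q-value-like
    significance, smaller = better). Header lines starting with ``#`` or with
    a non-numeric start field are skipped, matching the loose headers that
    loop callers emit.
    """
    if score_column is not None and score_column < 6:
        raise ConfigurationError(
            f"score_column {score_column} overlaps the six coordinate columns"
        )
    out: list[Loop] = []
    with _open_text(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 columns")
            if not (_is_int(fields[1]) and _is_int(fields[4])):
                continue  # caller-style header row
            score: Optional[float] = None
            if score_column is not None:
                if score_column >= len(fields):
                    raise ConfigurationError(
                        f"{path}:{lineno}: score_column {score_column} out of "
                        f"range for {len(fields)}-column row"
                    )
                score = float(fields[score_column])
                if score_threshold is not None and score > score_threshold:
                    continue
            try:
                a1 = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                a2 = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            out.append(Loop(a1, a2, score=score, sample_id=sample_id))
    return out


def write_bedpe_loops(path: PathLike, loops: Sequence[Loop]) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            a, b = lp.anchor1, lp.anchor2
            row = [a.chrom, a.start, a.end, b.chrom, b.start, b.end]
            if lp.score is not None:
                row.append(repr(lp.score))
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_narrowpeak(path: PathLike, sample_id: str = "") -> list[Peak]:
    """Read a narrowPeak / BED mixed-dialect file into peaks.

    The signalValue column (7th) populates ``signal`` when present; 3-6 column
    BED rows yield peaks without signal.
    """
    out: list[Peak] = []
    with _open_text(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            signal = float(fields[6]) if len(fields) >= 7 else None
            out.append(Peak(iv, signal=signal, sample_id=sample_id))
    return out


def write_narrowpeak(path: PathLike, peaks: Sequence[Peak]) -> None:
    with open(path, "w") as fh:
        for pk in peaks:
            iv = pk.interval
            if pk.signal is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t."
                    f"\t{pk.signal!r}\t-1\t-1\t-1\n"
                )
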