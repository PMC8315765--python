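"""Seeded generator for a coherent toy genome with known SNP-to-gene truth.

Emits every input the linking pipeline consumes — TADs, a GTF, per-sample
expression, H3K27ac peaks, enhancer-promoter loops, GWAS loci with LD
proxies, background SNPs, eQTL gene sets — plus the ground-truth locus-to-
gene map, so the full pipeline is testable end to end without downloads.

The generator is a pure function of its config: one root seed is split into
independent substreams per component (fixed substream indices), so the same
config yields byte-identical files and adding a new output never perturbs
existing draws.

Geometry is constructed so the intended truth map is *exactly* the link set
the pipeline recovers on noise-free data: enhancer midpoints and TSSs keep
clear of TAD boundaries (loop anchors never straddle a boundary), TSSs keep
clear of enhancers and of each other (the 5 kb loop rule and 1 kb promoter
rule each see exactly one gene per anchor/SNP), LD proxies are
rejection-placed away from foreign anchors and promoters, and noise-loop
anchors avoid all GWAS variants. See docs/methods.md for what this does and
does not emulate about real HiChIP data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .core_io import (
    ConfigurationError,
    GenomicInterval,
    Loop,
    Peak,
    write_bed,
    write_narrowpeak,
)

PathLike = Union[str, Path]

# substream indices (fixed; append-only)
_SS_TADS = 0
_SS_ENHANCERS = 1
_SS_GENES = 2
_SS_EXPRESSION = 3
_SS_TRUTH_LOOPS = 4
_SS_GWAS = 5
_SS_NOISE_LOOPS = 6
_SS_BACKGROUND_SNPS = 7
_SS_BACKGROUND_PEAKS = 8
_SS_EQTL = 9
_SS_SCORES = 10

_MAX_TRIES = 500


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the toy genome.

    Defaults emulate the statistical structure the analysis assumes: ~90% of
    loops within TADs, loop distances gamma-distributed with median ~250 kb,
    risk SNPs inside active enhancers, eQTL sets that are a noisy view of the
    truth (per-gene dropout, per-locus spurious additions).
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    n_tads_per_chrom: int = 10
    n_genes: int = 300
    n_noncoding_genes: int = 20
    expressed_fraction: float = 0.8
    tpm_mu: float = 1.0
    tpm_sigma: float = 1.0
    n_enhancers: int = 150
    enhancer_width: int = 2_000
    n_truth_loops: int = 800
    n_noise_loops: int = 200
    fraction_within_tads: float = 0.9
    loop_share_fraction: float = 0.6
    loop_gamma_shape: float = 2.0
    loop_gamma_scale: float = 150_000.0
    bin_size: int = 5_000
    n_gwas_loci: int = 40
    proxies_per_locus: int = 5
    proxy_spread: int = 20_000
    eqtl_dropout: float = 0.2
    eqtl_spurious_rate: float = 0.2
    n_background_snps: int = 2_000
    n_background_peaks: int = 100
    sample_ids: tuple[str, ...] = ("KC_unstim", "KC_stim")
    diseases: tuple[str, ...] = ("psoriasis", "eczema", "melanoma")

    def __post_init__(self) -> None:
        for name in ("expressed_fraction", "fraction_within_tads", "loop_share_fraction",
                     "eqtl_dropout", "eqtl_spurious_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in ("n_chroms", "chrom_length", "n_tads_per_chrom", "n_genes", "n_enhancers", "bin_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        tad_len = self.chrom_length / self.n_tads_per_chrom
        if tad_len < 8 * self.bin_size:
            raise ConfigurationError(
                f"TADs of ~{tad_len:.0f} bp cannot host {self.bin_size} bp "
                "anchors away from their boundaries"
            )
        if self.n_gwas_loci > self.n_enhancers:
            raise ConfigurationError("more GWAS loci than enhancers")
        # crude capacity check for rejection placement
        footprint = (
            self.n_enhancers * 12_000
            + (self.n_genes + self.n_noncoding_genes) * 12_000
        )
        if footprint > 0.7 * self.n_chroms * self.chrom_length:
            raise ConfigurationError(
                "genome too small for the requested gene/enhancer density"
            )


@dataclass(frozen=True)
class _Gene:
    gene_id: str
    gene_name: str
    chrom: str
    tss: int  # 0-based
    strand: str
    biotype: str
    tad: int
    transcript_lengths: tuple[int, ...]


@dataclass(frozen=True)
class _Enhancer:
    enh_id: str
    chrom: str
    mid: int
    tad: int

    def interval(self, width: int) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.mid - width // 2, self.mid + width // 2)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the file bundle."""

    targets: dict[str, frozenset[str]]  # locus_id -> target gene_ids
    locus_disease: dict[str, str]
    loop_labels: list[str]  # "truth" | "noise", aligned with `loops`
    loops: list[Loop]  # distinct loops (a shared loop appears once here)
    loop_samples: list[tuple[str, ...]]  # cell states each loop is called in
    gene_expressed: dict[str, bool]  # expressed in every sample


@dataclass
class SimulatedBundle:
    """Paths of every emitted file, keyed by role."""

    out_dir: Path
    gtf: Path
    expression: Path
    tads: Path
    loops_by_sample: dict[str, Path]
    peaks_by_sample: dict[str, Path]
    gwas_snps: Path
    background_snps: Path
    eqtl: Path
    truth_genes: Path
    truth_loops: Path
    manifest: Path


def _bin_around(chrom: str, mid: int, bin_size: int) -> GenomicInterval:
    return GenomicInterval(chrom, mid - bin_size // 2, mid + bin_size // 2)


def _place_points(
    rng: np.random.Generator,
    n: int,
    lo: int,
    hi: int,
    boundaries: np.ndarray,
    boundary_margin: int,
    occupied: list[int],
    min_spacing: int,
    what: str,
) -> list[int]:
    """Rejection-sample n integer positions in [lo, hi) keeping
    ``boundary_margin`` from every boundary and ``min_spacing`` from both
    previously occupied and newly placed points."""
    placed: list[int] = []
    taken = sorted(occupied)
    for _ in range(n):
        for _try in range(_MAX_TRIES):
            p = int(rng.integers(lo, hi))
            if boundaries.size and np.min(np.abs(boundaries - p)) < boundary_margin:
                continue
            idx = np.searchsorted(taken, p)
            near = []
            if idx > 0:
                near.append(taken[idx - 1])
            if idx < len(taken):
                near.append(taken[idx])
            if near and min(abs(p - q) for q in near) < min_spacing:
                continue
            placed.append(p)
            taken.insert(int(np.searchsorted(taken, p)), p)
            break
        else:
            raise ConfigurationError(
                f"could not place {what}: genome too crowded after {_MAX_TRIES} tries"
            )
    return placed


def simulate_dataset(
    cfg: SimulationConfig, out_dir: PathLike
) -> tuple[SimulatedBundle, SyntheticTruth]:
    """Generate the full input bundle plus ground truth under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(cfg.seed)
    streams = {i: np.random.default_rng(s) for i, s in enumerate(root.spawn(12))}
    chroms = [f"c{i + 1}" for i in range(cfg.n_chroms)]
    margin = cfg.bin_size  # keeps every anchor bin clear of TAD boundaries

    # --- TADs: jittered equal tiling per chromosome -----------------------
    rng = streams[_SS_TADS]
    tads: list[GenomicInterval] = []
    boundaries_by_chrom: dict[str, np.ndarray] = {}
    for chrom in chroms:
        step = cfg.chrom_length / cfg.n_tads_per_chrom
        cuts = [0]
        for k in range(1, cfg.n_tads_per_chrom):
            jitter = rng.uniform(-0.1, 0.1) * step
            cuts.append(int(k * step + jitter))
        cuts.append(cfg.chrom_length)
        cuts = sorted(cuts)
        boundaries_by_chrom[chrom] = np.array(cuts)
        for a, b in zip(cuts, cuts[1:]):
            tads.append(GenomicInterval(chrom, a, b))

    def tad_index(chrom: str, pos: int) -> int:
        return int(np.searchsorted(boundaries_by_chrom[chrom], pos, side="right")) - 1

    # --- enhancers --------------------------------------------------------
    rng = streams[_SS_ENHANCERS]
    enhancers: list[_Enhancer] = []
    per_chrom = np.array_split(np.arange(cfg.n_enhancers), cfg.n_chroms)
    occupied: dict[str, list[int]] = {c: [] for c in chroms}
    for chrom, idxs in zip(chroms, per_chrom):
        mids = _place_points(
            rng, len(idxs), margin, cfg.chrom_length - margin,
            boundaries_by_chrom[chrom], margin, occupied[chrom], 12_000, "enhancer",
        )
        occupied[chrom].extend(mids)
        for i, mid in zip(idxs, mids):
            enhancers.append(_Enhancer(f"ENH{i:04d}", chrom, mid, tad_index(chrom, mid)))

    # --- genes (TSSs clear of enhancers and of each other) ----------------
    rng = streams[_SS_GENES]
    genes: list[_Gene] = []
    n_total_genes = cfg.n_genes + cfg.n_noncoding_genes
    per_chrom_genes = np.array_split(np.arange(n_total_genes), cfg.n_chroms)
    for chrom, idxs in zip(chroms, per_chrom_genes):
        tss_list = _place_points(
            rng, len(idxs), margin, cfg.chrom_length - margin,
            boundaries_by_chrom[chrom], margin, occupied[chrom], 12_000, "gene TSS",
        )
        occupied[chrom].extend(tss_list)
        for i, tss in zip(idxs, tss_list):
            coding = i < cfg.n_genes
            strand = "+" if rng.random() < 0.5 else "-"
            n_tx = int(rng.integers(1, 4))
            lengths = tuple(int(rng.integers(2_000, 20_000)) for _ in range(n_tx))
            genes.append(
                _Gene(
                    gene_id=f"GENE{i:04d}",
                    gene_name=f"GN{i:04d}",
                    chrom=chrom,
                    tss=tss,
                    strand=strand,
                    biotype="protein_coding" if coding else "lncRNA",
                    tad=tad_index(chrom, tss),
                    transcript_lengths=lengths,
                )
            )
    coding_genes = [g for g in genes if g.biotype == "protein_coding"]

    # --- expression (truth-eligible genes expressed in every sample) ------
    rng = streams[_SS_EXPRESSION]
    n_expressed = round(cfg.expressed_fraction * cfg.n_genes)
    expressed_ids = set(
        rng.choice([g.gene_id for g in coding_genes], size=n_expressed, replace=False)
    )
    tpm: dict[str, dict[str, float]] = {}
    for g in genes:
        row = {}
        for s in cfg.sample_ids:
            if g.gene_id in expressed_ids:
                row[s] = 1.0 + float(rng.lognormal(cfg.tpm_mu, cfg.tpm_sigma))
            else:
                row[s] = float(rng.uniform(0.0, 0.99))
        tpm[g.gene_id] = row
    expressed_coding = [g for g in coding_genes if g.gene_id in expressed_ids]

    # --- truth enhancer-promoter loops ------------------------------------
    rng = streams[_SS_TRUTH_LOOPS]
    genes_by_chrom_tad: dict[tuple[str, int], list[_Gene]] = {}
    genes_by_chrom: dict[str, list[_Gene]] = {}
    for g in expressed_coding:
        genes_by_chrom_tad.setdefault((g.chrom, g.tad), []).append(g)
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    truth_loops: list[Loop] = []
    truth_loop_samples: list[tuple[str, ...]] = []
    loop_target: list[tuple[_Enhancer, _Gene]] = []
    used_pairs: set[tuple[str, str]] = set()
    loops_of_enhancer: dict[str, list[_Gene]] = {e.enh_id: [] for e in enhancers}
    guard = 0
    while len(truth_loops) < cfg.n_truth_loops:
        guard += 1
        if guard > 50 * cfg.n_truth_loops + _MAX_TRIES:
            raise ConfigurationError("could not construct the requested truth loops")
        e = enhancers[int(rng.integers(len(enhancers)))]
        within = rng.random() < cfg.fraction_within_tads
        if within:
            cands = genes_by_chrom_tad.get((e.chrom, e.tad), [])
        else:
            cands = [g for g in genes_by_chrom.get(e.chrom, []) if g.tad != e.tad]
        if not cands:
            continue
        d = rng.gamma(cfg.loop_gamma_shape, cfg.loop_gamma_scale)
        sign = 1 if rng.random() < 0.5 else -1
        target = e.mid + sign * d
        order = sorted(cands, key=lambda g: (abs(g.tss - target), g.gene_id))
        pick: Optional[_Gene] = None
        for g in order:
            if (e.enh_id, g.gene_id) not in used_pairs:
                pick = g
                break
        if pick is None:
            continue
        used_pairs.add((e.enh_id, pick.gene_id))
        sample = cfg.sample_ids[int(rng.integers(len(cfg.sample_ids)))]
        shared = rng.random() < cfg.loop_share_fraction
        lp = Loop(
            _bin_around(e.chrom, e.mid, cfg.bin_size),
            _bin_around(pick.chrom, pick.tss, cfg.bin_size),
            sample_id=sample,
        )
        truth_loops.append(lp)
        truth_loop_samples.append(cfg.sample_ids if shared else (sample,))
        loop_target.append((e, pick))
        loops_of_enhancer[e.enh_id].append(pick)

    # --- GWAS loci: leads inside loop-bearing enhancers -------------------
    rng = streams[_SS_GWAS]
    bearing = [e for e in enhancers if loops_of_enhancer[e.enh_id]]
    if len(bearing) < cfg.n_gwas_loci:
        raise ConfigurationError(
            f"only {len(bearing)} enhancers carry loops; cannot build "
            f"{cfg.n_gwas_loci} GWAS loci"
        )
    chosen = [
        bearing[i]
        for i in sorted(rng.choice(len(bearing), size=cfg.n_gwas_loci, replace=False))
    ]
    # foreign-anchor index for proxy rejection
    anchors_by_chrom: dict[str, list[tuple[int, int, str]]] = {c: [] for c in chroms}
    for lp, (e, g) in zip(truth_loops, loop_target):
        anchors_by_chrom[e.chrom].append((lp.anchor1.start, lp.anchor1.end, e.enh_id))
        anchors_by_chrom[g.chrom].append((lp.anchor2.start, lp.anchor2.end, e.enh_id))
    tss_by_chrom = {
        c: np.sort(np.array([g.tss for g in genes if g.chrom == c])) for c in chroms
    }

    def near_tss(chrom: str, p: int, w: int = 1_500) -> bool:
        arr = tss_by_chrom[chrom]
        i = int(np.searchsorted(arr, p))
        for j in (i - 1, i):
            if 0 <= j < arr.size and abs(int(arr[j]) - p) <= w:
                return True
        return False

    def in_foreign_anchor(chrom: str, p: int, own: str) -> bool:
        return any(s <= p < e_ for s, e_, eid in anchors_by_chrom[chrom] if eid != own)

    gwas_rows: list[tuple[str, str, int, str, float, str]] = []
    truth_targets: dict[str, frozenset[str]] = {}
    locus_disease: dict[str, str] = {}
    half_e = cfg.enhancer_width // 2
    for i, e in enumerate(chosen):
        locus_id = f"rs{1000 + i}"
        disease = cfg.diseases[i % len(cfg.diseases)]
        lead = int(rng.integers(e.mid - half_e, e.mid + half_e))
        gwas_rows.append((locus_id, e.chrom, lead, locus_id, 1.0, disease))
        for j in range(cfg.proxies_per_locus):
            placed = None
            for _try in range(_MAX_TRIES):
                p = int(rng.integers(lead - cfg.proxy_spread, lead + cfg.proxy_spread))
                if p < 0 or p >= cfg.chrom_length:
                    continue
                if near_tss(e.chrom, p) or in_foreign_anchor(e.chrom, p, e.enh_id):
                    continue
                placed = p
                break
            if placed is None:  # fall back to the (always safe) enhancer body
                placed = int(rng.integers(e.mid - half_e, e.mid + half_e))
            r2 = float(rng.uniform(0.8, 1.0))
            gwas_rows.append((f"{locus_id}_p{j}", e.chrom, placed, locus_id, r2, disease))
        truth_targets[locus_id] = frozenset(
            g.gene_id for g in loops_of_enhancer[e.enh_id]
        )
        locus_disease[locus_id] = disease

    # --- noise loops: random bins avoiding every GWAS variant -------------
    rng = streams[_SS_NOISE_LOOPS]
    variant_pos_by_chrom: dict[str, np.ndarray] = {
        c: np.sort(np.array([r[2] for r in gwas_rows if r[1] == c], dtype=np.int64))
        for c in chroms
    }

    def hits_variant(chrom: str, lo: int, hi: int) -> bool:
        arr = variant_pos_by_chrom[chrom]
        i = int(np.searchsorted(arr, lo))
        return i < arr.size and arr[i] < hi

    def tads_contain(chrom: str, a: GenomicInterval, b: GenomicInterval) -> bool:
        for cand in tads:
            if cand.chrom == chrom and cand.start <= a.start and b.end <= cand.end:
                return True
        return False

    noise_loops: list[Loop] = []
    noise_loop_samples: list[tuple[str, ...]] = []
    half_bin = cfg.bin_size // 2
    while len(noise_loops) < cfg.n_noise_loops:
        chrom = chroms[int(rng.integers(len(chroms)))]
        within = rng.random() < cfg.fraction_within_tads
        for _try in range(_MAX_TRIES):
            m1 = int(rng.integers(half_bin, cfg.chrom_length - half_bin))
            d = max(cfg.bin_size, int(rng.gamma(cfg.loop_gamma_shape, cfg.loop_gamma_scale)))
            sign = 1 if rng.random() < 0.5 else -1
            m2 = m1 + sign * d
            if not (half_bin <= m2 < cfg.chrom_length - half_bin):
                continue
            a = _bin_around(chrom, min(m1, m2), cfg.bin_size)
            b = _bin_around(chrom, max(m1, m2), cfg.bin_size)
            if hits_variant(chrom, a.start, a.end) or hits_variant(chrom, b.start, b.end):
                continue
            if tads_contain(chrom, a, b) != within:
                continue
            sample = cfg.sample_ids[int(rng.integers(len(cfg.sample_ids)))]
            shared = rng.random() < cfg.loop_share_fraction
            noise_loops.append(Loop(a, b, sample_id=sample))
            noise_loop_samples.append(cfg.sample_ids if shared else (sample,))
            break
        else:
            raise ConfigurationError("could not place noise loops in the geometry")

    # --- background SNPs ---------------------------------------------------
    rng = streams[_SS_BACKGROUND_SNPS]
    background_rows = []
    for i in range(cfg.n_background_snps):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(0, cfg.chrom_length))
        background_rows.append((f"bg{i}", chrom, pos, f"bg{i}", 1.0, ""))

    # --- peaks -------------------------------------------------------------
    rng = streams[_SS_BACKGROUND_PEAKS]
    background_peaks = []
    for _ in range(cfg.n_background_peaks):
        chrom = chroms[int(rng.integers(len(chroms)))]
        s = int(rng.integers(0, cfg.chrom_length - 1_000))
        background_peaks.append(GenomicInterval(chrom, s, s + 1_000))
    peaks_by_sample: dict[str, list[Peak]] = {}
    for s in cfg.sample_ids:
        pk: list[Peak] = []
        for e in enhancers:
            pk.append(Peak(e.interval(cfg.enhancer_width), signal=5.0, sample_id=s))
        for g in genes:
            if g.gene_id in expressed_ids:
                pk.append(
                    Peak(GenomicInterval(g.chrom, g.tss - 500, g.tss + 500), signal=3.0, sample_id=s)
                )
        for iv in background_peaks:
            pk.append(Peak(iv, signal=1.0, sample_id=s))
        pk.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
        peaks_by_sample[s] = pk

    # --- eQTL sets: truth minus dropout plus spurious ----------------------
    rng = streams[_SS_EQTL]
    eqtl_rows: list[tuple[str, str]] = []
    expressed_sorted = sorted(g.gene_id for g in expressed_coding)
    for locus_id in sorted(truth_targets):
        targets = sorted(truth_targets[locus_id])
        kept = [g for g in targets if rng.random() >= cfg.eqtl_dropout]
        n_spurious = int(rng.binomial(len(targets), cfg.eqtl_spurious_rate))
        pool = [g for g in expressed_sorted if g not in truth_targets[locus_id]]
        spurious = (
            list(rng.choice(pool, size=min(n_spurious, len(pool)), replace=False))
            if n_spurious
            else []
        )
        for g in kept + sorted(spurious):
            eqtl_rows.append((locus_id, g))

    # --- loop scores -------------------------------------------------------
    rng = streams[_SS_SCORES]
    all_loops = truth_loops + noise_loops
    loop_samples = truth_loop_samples + noise_loop_samples
    labels = ["truth"] * len(truth_loops) + ["noise"] * len(noise_loops)
    scores = rng.uniform(1e-6, 0.01, size=len(all_loops))
    all_loops = [
        Loop(lp.anchor1, lp.anchor2, score=float(q), sample_id=lp.sample_id)
        for lp, q in zip(all_loops, scores)
    ]

    # --- write the bundle ---------------------------------------------------
    paths = _write_bundle(
        out, cfg, chroms, tads, genes, tpm, all_loops, labels, loop_samples,
        loop_target, peaks_by_sample, gwas_rows, background_rows, eqtl_rows,
        truth_targets,
    )
    truth = SyntheticTruth(
        targets=truth_targets,
        locus_disease=locus_disease,
        loop_labels=labels,
        loops=all_loops,
        loop_samples=loop_samples,
        gene_expressed={g.gene_id: (g.gene_id in expressed_ids) for g in genes},
    )
    return paths, truth


def _write_bundle(
    out: Path,
    cfg: SimulationConfig,
    chroms: Sequence[str],
    tads: Sequence[GenomicInterval],
    genes: Sequence[_Gene],
    tpm: dict[str, dict[str, float]],
    all_loops: Sequence[Loop],
    labels: Sequence[str],
    loop_samples: Sequence[tuple[str, ...]],
    loop_target: Sequence[tuple[_Enhancer, _Gene]],
    peaks_by_sample: dict[str, list[Peak]],
    gwas_rows: Sequence[tuple],
    background_rows: Sequence[tuple],
    eqtl_rows: Sequence[tuple[str, str]],
    truth_targets: dict[str, frozenset[str]],
) -> SimulatedBundle:
    tads_path = out / "tads.bed"
    write_bed(tads_path, tads)

    gtf_path = out / "genes.gtf"
    with open(gtf_path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.tss, g.gene_id)):
            span = max(g.transcript_lengths)
            if g.strand == "+":
                g_start, g_end = g.tss + 1, g.tss + span
            else:
                g_start, g_end = max(1, g.tss + 2 - span), g.tss + 1
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
                f'gene_type "{g.biotype}";'
            )
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g_start}\t{g_end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for k, length in enumerate(g.transcript_lengths):
                if g.strand == "+":
                    t_start, t_end = g.tss + 1, g.tss + length
                else:
                    t_start, t_end = max(1, g.tss + 2 - length), g.tss + 1
                t_attrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t{k + 1}"; '
                    f'gene_name "{g.gene_name}"; gene_type "{g.biotype}";'
                )
                fh.write(
                    f"{g.chrom}\tsim\ttranscript\t{t_start}\t{t_end}\t.\t{g.strand}\t.\t{t_attrs}\n"
                )

    expr_path = out / "expression.tsv"
    with open(expr_path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(cfg.sample_ids) + "\n")
        for g in sorted(genes, key=lambda g: g.gene_id):
            vals = "\t".join(f"{tpm[g.gene_id][s]:.6g}" for s in cfg.sample_ids)
            fh.write(f"{g.gene_id}\t{vals}\n")

    loops_by_sample: dict[str, Path] = {}
    for s in cfg.sample_ids:
        p = out / f"loops_{s}.bedpe"
        with open(p, "w") as fh:
            fh.write("#chr1\tstart1\tend1\tchr2\tstart2\tend2\tqvalue\n")
            sample_loops = sorted(
                (lp for lp, members in zip(all_loops, loop_samples) if s in members),
                key=lambda lp: (
                    lp.anchor1.chrom, lp.anchor1.start, lp.anchor2.chrom, lp.anchor2.start,
                ),
            )
            for lp in sample_loops:
                a, b = lp.anchor1, lp.anchor2
                fh.write(
                    f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
                    f"\t{lp.score:.6g}\n"
                )
        loops_by_sample[s] = p

    peaks_paths: dict[str, Path] = {}
    for s, pk in peaks_by_sample.items():
        p = out / f"peaks_{s}.narrowPeak"
        write_narrowpeak(p, pk)
        peaks_paths[s] = p

    gwas_path = out / "gwas_snps.tsv"
    with open(gwas_path, "w") as fh:
        fh.write("snp_id\tchrom\tpos_1based\tlocus_id\tr2\tdisease\n")
        for snp_id, chrom, pos0, locus_id, r2, disease in gwas_rows:
            fh.write(f"{snp_id}\t{chrom}\t{pos0 + 1}\t{locus_id}\t{r2:.4f}\t{disease}\n")

    bg_path = out / "background_snps.tsv"
    with open(bg_path, "w") as fh:
        fh.write("snp_id\tchrom\tpos_1based\tlocus_id\tr2\tdisease\n")
        for snp_id, chrom, pos0, locus_id, r2, disease in background_rows:
            fh.write(f"{snp_id}\t{chrom}\t{pos0 + 1}\t{locus_id}\t{r2:.4f}\t{disease}\n")

    eqtl_path = out / "eqtl.tsv"
    with open(eqtl_path, "w") as fh:
        fh.write("locus_id\tgene_id\n")
        for locus_id, gene_id in eqtl_rows:
            fh.write(f"{locus_id}\t{gene_id}\n")

    truth_genes_path = out / "truth_genes.tsv"
    with open(truth_genes_path, "w") as fh:
        fh.write("locus_id\tgene_id\n")
        for locus_id in sorted(truth_targets):
            for gene_id in sorted(truth_targets[locus_id]):
                fh.write(f"{locus_id}\t{gene_id}\n")

    truth_loops_path = out / "truth_loops.tsv"
    with open(truth_loops_path, "w") as fh:
        fh.write(
            "chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tsamples\tlabel"
            "\tenhancer_id\tgene_id\n"
        )
        for i, (lp, label) in enumerate(zip(all_loops, labels)):
            a, b = lp.anchor1, lp.anchor2
            if label == "truth":
                e, g = loop_target[i]
                extra = f"{e.enh_id}\t{g.gene_id}"
            else:
                extra = "\t"
            members = ";".join(loop_samples[i])
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
                f"\t{members}\t{label}\t{extra}\n"
            )

    manifest_path = out / "manifest.json"
    files = {
        "tads": tads_path, "gtf": gtf_path, "expression": expr_path,
        "gwas_snps": gwas_path, "background_snps": bg_path, "eqtl": eqtl_path,
        "truth_genes": truth_genes_path, "truth_loops": truth_loops_path,
        **{f"loops_{s}": p for s, p in loops_by_sample.items()},
        **{f"peaks_{s}": p for s, p in peaks_paths.items()},
    }
    digests = {
        k: hashlib.sha256(p.read_bytes()).hexdigest() for k, p in sorted(files.items())
    }
    manifest_path.write_text(
        json.dumps({"config": asdict(cfg), "digests": digests}, indent=2, sort_keys=True)
        + "\n"
    )
    return SimulatedBundle(
        out_dir=out,
        gtf=gtf_path,
        expression=expr_path,
        tads=tads_path,
        loops_by_sample=loops_by_sample,
        peaks_by_sample=peaks_paths,
        gwas_snps=gwas_path,
        background_snps=bg_path,
        eqtl=eqtl_path,
        truth_genes=truth_genes_path,
        truth_loops=truth_loops_path,
        manifest=manifest_path,
    )
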