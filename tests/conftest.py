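import numpy as np
import pytest

from loopgene.annotate import TssRecord
from loopgene.core_io import GenomicInterval, Loop, Peak
from loopgene.loci import LocusSet, Variant
from loopgene.pipeline import PipelineConfig, run_pipeline
from loopgene.synthetic_data import SimulationConfig, simulate_dataset


def make_tss(gene_id, chrom, tss, transcript=None, name=None):
    return TssRecord(
        gene_id=gene_id,
        gene_name=name or gene_id,
        transcript_id=transcript or f"{gene_id}.t1",
        chrom=chrom,
        tss=tss,
        strand="+",
        biotype="protein_coding",
    )


def make_locus(locus_id, chrom, positions, disease=""):
    """Locus with its lead at the first position (0-based positions)."""
    variants = [Variant(locus_id, chrom, positions[0], 1.0, locus_id)] + [
        Variant(f"{locus_id}_p{i}", chrom, p, 0.9, locus_id)
        for i, p in enumerate(positions[1:])
    ]
    lo, hi = min(positions), max(positions)
    return LocusSet(locus_id, tuple(variants), GenomicInterval(chrom, lo, hi + 1), disease)


def random_instance(rng, n_snps=20, n_loops=50, n_tss=30, n_peaks=30, span=2_000_000):
    """A random chromosome's worth of loci, loops, peaks and TSSs for oracle
    comparisons. Coordinates are intentionally dense so windows overlap often."""
    chrom = "c1"
    loci = []
    for i in range(max(1, n_snps // 4)):
        k = int(rng.integers(1, 5))
        positions = sorted(int(rng.integers(0, span)) for _ in range(k))
        loci.append(make_locus(f"L{i}", chrom, positions))
    loops = []
    for i in range(n_loops):
        s1 = int(rng.integers(0, span - 5_000))
        w1 = int(rng.integers(1_000, 5_000))
        s2 = int(rng.integers(0, span - 5_000))
        w2 = int(rng.integers(1_000, 5_000))
        sample = f"s{int(rng.integers(2))}"
        loops.append(
            Loop(
                GenomicInterval(chrom, s1, s1 + w1),
                GenomicInterval(chrom, s2, s2 + w2),
                sample_id=sample,
            )
        )
    tss = [
        make_tss(f"G{i}", chrom, int(rng.integers(0, span)), transcript=f"G{i}.t1")
        for i in range(n_tss)
    ]
    peaks = []
    for i in range(n_peaks):
        s = int(rng.integers(0, span - 3_000))
        w = int(rng.integers(500, 3_000))
        sample = f"s{int(rng.integers(2))}"
        peaks.append(Peak(GenomicInterval(chrom, s, s + w), sample_id=sample))
    return loci, loops, tss, peaks


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """Default-scale simulated bundle shared by the slower tests."""
    out = tmp_path_factory.mktemp("sim_default")
    cfg = SimulationConfig(seed=11)
    bundle, truth = simulate_dataset(cfg, out)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def default_run(default_sim):
    cfg, bundle, truth = default_sim
    result = run_pipeline(PipelineConfig.for_bundle(bundle))
    return cfg, bundle, truth, result
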