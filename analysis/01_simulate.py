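#!/usr/bin/env python
"""Generate the study's input bundle: a two-chromosome toy genome with TADs,
genes, H3K27ac peaks, enhancer-promoter loops, GWAS loci with LD proxies and
partially concordant eQTL sets, plus the ground-truth SNP-to-gene map.

Writes the bundle under results/sim/ so the later steps can load it.
"""

from pathlib import Path

from loopgene.synthetic_data import SimulationConfig, simulate_dataset

SEED = 2024
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    bundle, truth = simulate_dataset(cfg, OUT)
    n_targets = sum(len(v) for v in truth.targets.values())
    print(f"wrote bundle to {OUT}")
    print(f"  {cfg.n_chroms} chromosomes x {cfg.chrom_length / 1e6:.0f} Mb, "
          f"{cfg.n_genes} protein-coding genes, {cfg.n_enhancers} enhancers")
    print(f"  {len(truth.loops)} loops ({cfg.n_truth_loops} enhancer-promoter, "
          f"{cfg.n_noise_loops} noise), target within-TAD fraction "
          f"{cfg.fraction_within_tads}")
    print(f"  {len(truth.targets)} GWAS loci with {n_targets} true target genes "
          f"({n_targets / len(truth.targets):.1f} per locus)")


if __name__ == "__main__":
    main()
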