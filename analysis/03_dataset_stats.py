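#!/usr/bin/env python
"""Dataset-level statistics of the loop compendium: anchor-midpoint distance
distribution, fraction of loops contained within TADs, replicate-style
concordance between the two cell states, and GWAS-SNP-in-peak permutation
enrichment. Writes results/dataset_stats.json.
"""

import json
from pathlib import Path

from loopgene.core_io import read_bed, read_bedpe_loops, read_narrowpeak
from loopgene.loci import build_loci
from loopgene.metrics import (
    loop_distance_stats,
    loop_set_concordance,
    snp_peak_enrichment,
    tad_overlap_stats,
)

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "results" / "sim"
SAMPLES = ("KC_unstim", "KC_stim")


def main() -> None:
    loops = {
        s: read_bedpe_loops(SIM / f"loops_{s}.bedpe", sample_id=s) for s in SAMPLES
    }
    all_loops = [lp for ls in loops.values() for lp in ls]
    tads = read_bed(SIM / "tads.bed")

    dist = loop_distance_stats(all_loops)
    tad = tad_overlap_stats(all_loops, tads)
    conc = loop_set_concordance(loops[SAMPLES[0]], loops[SAMPLES[1]])
    snps = [v for l in build_loci(SIM / "gwas_snps.tsv") for v in l.variants]
    bg = [v for l in build_loci(SIM / "background_snps.tsv", r2_threshold=0.0)
          for v in l.variants]
    peaks = read_narrowpeak(SIM / f"peaks_{SAMPLES[0]}.narrowPeak", sample_id=SAMPLES[0])
    enr = snp_peak_enrichment(snps, peaks, bg, n_perm=1000, seed=2024)

    payload = {
        "distance_stats": dist,
        "tad_stats": {"n_within": tad.n_within, "n_crossing": tad.n_crossing,
                      "fraction_within": tad.fraction_within},
        "state_concordance": conc,
        "snp_peak_enrichment": {
            "observed_fraction": enr.observed_fraction,
            "null_mean_fraction": enr.null_mean_fraction,
            "fold": enr.fold, "p_value": enr.p_value,
        },
    }
    out = ROOT / "results" / "dataset_stats.json"
    out.write_text(json.dumps(payload, indent=2) + "\n")
    print(f"wrote {out}")
    print(f"  median loop distance: {dist['median'] / 1000:.0f} kb (n={int(dist['n'])})")
    print(f"  loops within TADs: {tad.fraction_within:.1%}")
    print(f"  cross-state loop Jaccard (5 kb bins): {conc['jaccard']:.2f}")
    print(f"  GWAS SNPs in peaks: {enr.observed_fraction:.1%} vs null "
          f"{enr.null_mean_fraction:.1%} -> fold {enr.fold:.1f}, p = {enr.p_value:.2g}")


if __name__ == "__main__":
    main()
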