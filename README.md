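# loopgene

Link GWAS risk loci to candidate target genes through H3K27ac HiChIP
chromatin loops.

Most disease-associated variants land in non-coding regulatory DNA and often
regulate distal genes via enhancer–promoter loops rather than the nearest
gene. Given significant HiChIP loops, H3K27ac peaks, a gene annotation,
per-cell-type expression, and lead SNPs with LD proxies (r² ≥ 0.8),
`loopgene` assigns candidate genes to each locus by two rules:

* **loop**: a risk SNP lies inside one loop anchor and a transcript's TSS is
  within 5 kb of the other anchor;
* **promoter**: a risk SNP overlaps an H3K27ac peak and a TSS is within 1 kb
  of the SNP.

Transcripts are grouped by gene and genes filtered at ≥ 1 TPM in the cell
type that provided the evidence. On top of the link table the package
computes the evaluation statistics used to characterize such datasets:
eQTL concordance (recall, and precision — the share of linked genes with
eQTL support, colloquially printed as "specificity"), the fraction of loops
within TADs, loop-distance summaries, interactions per gene, permutation
enrichment of SNPs in peaks, and replicate loop-set concordance. A seeded
generator builds a coherent toy genome with known SNP→gene truth so the full
pipeline is testable end to end without downloads. See `docs/methods.md` for
the model and the generator's scope.

## Worked example

The analysis scripts run the whole study on simulated data
(`results/` holds their outputs):

```sh
python analysis/01_simulate.py      # toy genome + ground truth -> results/sim
python analysis/02_link_genes.py    # SNP -> gene assignment    -> results/link
python analysis/03_dataset_stats.py # loop/TAD/enrichment stats
python analysis/04_validation.py    # concordance vs eQTLs and vs truth
```

Output of a run (seed 2024):

```
linked 136 expressed genes across 40 loci -> results/link
  genes per locus: mean 4.88 over all loci
  per-disease gene counts: {'eczema': 51, 'melanoma': 66, 'psoriasis': 58}
  closest-gene classes (small LD blocks): {'all_closest_linked': 17,
    'some_closest_linked': 3, 'no_closest_linked': 20}
  gene-desert loci: 7
  loci whose linked set equals the simulated truth exactly: 40/40

  median loop distance: 219 kb (n=1607)
  loops within TADs: 89.4%
  cross-state loop Jaccard (5 kb bins): 0.61
  GWAS SNPs in peaks: 21.7% vs null 2.3% -> fold 9.2, p = 0.001

  vs eQTL sets: recall 77.8%, precision (aka specificity) 81.0%
  closed-form expectation at dropout 0.2, spurious 0.2: recall 80.0%,
    precision 80.0%
  vs generator truth: recall 100.0%, precision 100.0%
```

Reading this: the pipeline recovered every simulated locus's target genes
exactly (40/40), so the eQTL concordance numbers reflect only the noise
injected into the simulated eQTL sets — and they land on the closed-form
values implied by those noise rates. The loop compendium shows the expected
structure: ~90% of loops within TADs, median anchor distance ≈ 220 kb, risk
SNPs ~9-fold enriched in H3K27ac peaks over background. More than a third of
small-LD-block loci do not link their closest gene, the usual argument for
loop-based assignment over nearest-gene assignment.

The same pipeline runs on real FitHiChIP-style files through the CLI:

```sh
loopgene link --loops KC=loops.bedpe --peaks KC=peaks.narrowPeak \
  --gtf gencode.gtf.gz --expression tpm.tsv --snps gwas_snps.tsv \
  --tads tads.bed --eqtl eqtl.tsv --out out/
loopgene simulate --seed 7 --out sim/   # the toy-genome generator
loopgene stats --loops loops.bedpe --tads tads.bed ...
```

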