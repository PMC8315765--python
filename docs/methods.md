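# Methods

## The problem

Most GWAS risk variants for complex diseases fall in non-coding regulatory
DNA, and the gene a variant regulates is often not the nearest one: enhancers
contact distal promoters through chromatin loops. H3K27ac HiChIP assays the
active-chromatin interactome directly, producing a set of statistically
significant loops between fixed-size anchor bins together with H3K27ac peak
calls. `loopgene` implements the assignment of candidate target genes to
GWAS loci from such data, plus the statistics used to characterize the loop
compendium and to benchmark the assignments against eQTL evidence.

## Linking rules

Inputs: per-cell-type significant loops (BEDPE), H3K27ac peaks (narrowPeak),
a gene annotation (GTF), per-cell-type expression (TPM), and a table of lead
SNPs with LD proxies (precomputed r², default threshold r² ≥ 0.8; the strict
`>` reading is available as a flag since catalog conventions differ).

For every variant *v* of a locus and every transcript TSS *t* (protein-coding
transcripts by default):

* **Loop rule** — *v* lies inside one anchor of a loop (distance 0; a
  configurable `snp_anchor_window` relaxes this) and
  `dist(t, other anchor) ≤ 5 kb`. If *v* lies in both anchors, both
  directions are evaluated.
* **Promoter rule** — *v* overlaps any H3K27ac peak of the same cell type
  and `|t − v| ≤ 1 kb`. The peak needs not be a loop anchor: the rule
  captures variants sitting directly in active promoters.

Distances are `point_interval_distance`: 0 inside the half-open interval,
else the gap to the nearest contained base. All "within N kb" bounds are
inclusive. Internally all coordinates are 0-based half-open (BED); SNP and
TSS positions are converted from their 1-based source conventions on ingest.

Transcript-level hits are collapsed to gene level, deduplicated at
(locus, gene, evidence, cell type, loop identity), and genes are then
filtered at ≥ 1 TPM (inclusive) in the cell type that provided the evidence.
Genes absent from the expression table count as not expressed (logged).
Unexpressed rows stay in the link table flagged `expressed = 0` so the
filter is auditable; every reported gene set uses expressed rows only.

Locus-level summaries: unique expressed genes per disease (union over cell
types), genes per locus (means both over all loci and over loci with ≥ 1
gene, since "average genes per locus" is ambiguous between the two), the
closest-gene classification (for loci with LD block < 100 kb, strict: is the
set of nearest protein-coding genes — ties included — fully, partly, or not
at all contained in the linked set), and gene-desert loci (no protein-coding
TSS within 50 kb of the LD block, exclusive beyond the bound).

## Evaluation statistics

* **eQTL concordance** — per-locus gene sets from the pipeline vs an eQTL
  gene-set table. Pooled over loci: recall = |linked ∩ eQTL| / |eQTL|;
  the fraction |linked ∩ eQTL| / |linked| is a precision and is reported as
  such, though the field sometimes prints it as "specificity"; both labels
  appear in output. Per-locus matching is the default; a global-union mode
  exists because published figures do not always say which was used.
* **TAD containment** — a loop is *within* a TAD iff a single TAD fully
  contains both anchors; anything else (including an anchor straddling a
  boundary) is *crossing*. TADs must be non-overlapping per chromosome.
* **Loop distances** — anchor-midpoint separation of intra-chromosomal
  loops; the median is the lower median for even counts so it is always an
  observed value.
* **Interactions per gene** — for a gene set (e.g. genes upregulated on
  stimulation), the mean number of loops with an anchor within 5 kb of any
  TSS of the gene; zero-count genes stay in the mean.
* **SNP-in-peak enrichment** — observed fraction of risk SNPs inside any
  peak vs a permutation null drawing equally many SNPs from a user-supplied
  background pool without replacement; fold = observed / mean(null);
  p = (1 + #{null ≥ observed}) / (n_perm + 1) (add-one, so never exactly 0
  and super-uniform under the null). Fully seeded and bit-reproducible. The
  background pool and its matching are the caller's responsibility.
* **Loop-set concordance** — loops snapped to a 5 kb anchor-bin grid;
  Jaccard over binned anchor pairs, with optional slack in whole bins.

Inter-chromosomal loops are retained as link evidence but excluded from
distance and TAD statistics, where they are undefined.

## Synthetic data generator

`simulate_dataset` emits a complete, coherent input bundle plus the intended
locus→gene truth map. Default scale: 2 chromosomes × 10 Mb, 10 jittered TADs
each, 300 protein-coding genes (plus 20 lncRNA decoys for the biotype
filter), 150 enhancers, 1,000 loops (800 enhancer–promoter + 200 noise),
40 GWAS loci with 5 proxies each, 2,000 background SNPs, two cell states.
This runs the full pipeline in ~0.2 s while keeping every statistic away
from degenerate regimes.

What it emulates, and how:

* **Loops within TADs** — each loop carries a Bernoulli(0.9) within/crossing
  label realized exactly by construction (rejection against the same
  containment predicate the statistic uses), so the observed fraction is a
  clean binomial sample of `fraction_within_tads`.
* **Loop distances** — gamma(shape 2, scale 150 kb), median ≈ 252 kb,
  matching the few-hundred-kb scale of enhancer–promoter interactions; truth
  loops snap the promoter side to the nearest eligible gene, which blurs the
  distribution somewhat (observed medians run ~10% low at default scale).
* **Risk SNPs in enhancers** — every lead SNP sits inside an active enhancer
  (which carries a peak), so SNP-in-peak enrichment is strong against the
  uniform background (~3% of the genome is peak-covered).
* **Partially concordant eQTLs** — per locus, each truth gene is dropped
  with probability `eqtl_dropout` (d) and Binomial(K, `eqtl_spurious_rate`)
  (s) spurious expressed genes are added. Because the pipeline recovers the
  truth exactly (below), pooled concordance has closed forms: precision →
  1 − d, recall → (1 − d)/(1 − d + s). Defaults d = s = 0.2 put recall and
  precision at 0.8, the regime (tens of percent, nearer 1 than 0) where the
  statistics are informative.
* **Two cell states** — loops are shared between states with probability
  `loop_share_fraction` (0.6), giving the replicate-concordance statistic a
  non-trivial expected Jaccard of ≈ 0.6.

Exact truth recovery is guaranteed geometrically, not checked-and-patched:
enhancer midpoints and TSSs keep ≥ one anchor-bin width from TAD boundaries
(no straddling anchors), TSSs keep ≥ 12 kb from each other and ≥ 10 kb from
enhancers (each anchor/SNP sees exactly the intended gene under the 5 kb and
1 kb windows), LD proxies are rejection-placed outside foreign loop anchors
and promoter windows, and noise-loop anchors avoid all GWAS variants. Truth
target genes are expressed (> 1 TPM) in every cell state so the expression
filter never removes them. Consequently the expressed link set equals the
truth map even with noise loops present, which is what makes the eQTL
closed forms above exact rather than approximate.

All randomness flows from one root seed through fixed-index independent
substreams (TADs, enhancers, genes, expression, truth loops, GWAS, noise
loops, background SNPs, background peaks, eQTLs, scores), so the same config
yields byte-identical files and adding an output never perturbs earlier
draws.

What the generator does **not** emulate: read-level signal and peak-calling
noise, distance-dependent contact background, overlapping/nested regulatory
elements, LD structure beyond a positional scatter of proxies, expression
variation across states for truth genes, and loops whose calling depends on
coverage. Passing tests therefore demonstrate correctness of the interval
arithmetic, rule semantics, grouping/filtering logic and statistics — not
robustness to the messiness of real HiChIP calls.

## Numerical and design choices

* Lower median; inclusive window bounds; strict `<` for the 100 kb block
  cutoff and strict `>` beyond 50 kb for gene deserts (both phrased that way
  in common usage).
* Chromosome names: `chr1` and `1` normalize to one key for autosomes and
  X/Y; mitochondrial/scaffold names pass through verbatim rather than being
  guessed at.
* Closest-gene ties are all included; a locus on a chromosome with no TSS
  classifies as `no_closest_linked` with a warning.
* The permutation p-value uses the add-one estimator; a zero-coverage null
  yields an infinite fold with an explicit `degenerate` flag rather than a
  silent division error.
* Loop files are assumed pre-filtered to significant interactions; an
  optional score column + threshold re-filters at ingest for callers that
  ship everything.
* Errors are typed: `ConfigurationError` (bad parameters, unknown samples,
  empty TSS list — exit code 2 in the CLI) vs `DataError`/`ParseError`
  (malformed or contradictory inputs, named by file and line — exit code 3).

## Problem sizes

The test suite and the acceptance script run the default 1,000-loop /
40-locus scale for end-to-end checks, a 10,000-loop configuration for
TAD-fraction recovery, 100 random instances (≈ 30 loops × 20 TSS × ~10
variants each) per operation for brute-force oracle equivalence, and 500
null datasets × 199 permutations for p-value calibration. The whole suite
completes in well under a minute.

## Limitations

Candidate genes are unscored (no ABC-style weighting, no colocalization);
LD expansion, loop calling and TAD calling are upstream inputs; eQTL sets
are taken as given rather than queried from a database. The closest-gene and
gene-desert reports consider protein-coding TSSs only.
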