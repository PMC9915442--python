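# Methods

## Scope and model

`methylscape` re-implements, as a tested pipeline over synthetic data, a
whole-genome bisulfite-sequencing (WGBS) integration analysis for a
two-genotype (salinity-sensitive SS, salinity-tolerant ST) x
two-condition (control, salinity stress) plant experiment: methylcytosine
(mC) calling, 100-bp-bin DMR detection, DMR-to-gene/TE association,
metagene profiling, DEG/dmDEG integration, and small-RNA-directed TE
hypermethylation analysis. The pipeline starts at per-cytosine count
reports (the Bismark cytosine-report dialect); read alignment, GO
enrichment and genome-browser rendering are out of scope.

All internal coordinates are 0-based half-open; cytosine reports
(1-based) and GFF3 (1-based inclusive) are converted at the IO boundary.
Minus-strand trinucleotides are stored as read 5'->3' on the minus
strand, which makes the context rules (CG; CHG; CHH with H in {A,C,T};
CWA = {CAA, CTA} within CHH) strand-agnostic. Sites whose trinucleotide
window contains N or runs off the chromosome are excluded as
unclassifiable. Symmetric CG sites are kept per strand (no merge):
forward and reverse strands behave symmetrically under this model, and
per-strand handling keeps the report dialect round-trippable; a
strand-merge option exists.

## Statistical procedures

**Conversion error.** The bisulfite conversion-error rate per library is
the pooled methylated-read fraction over a biologically unmethylated
control sequence (the chloroplast's role, played here by a designated
control chromosome), with a Wilson 95% CI. Error rates are estimated per
sample since conversion efficiency is library-specific.

**mC calling.** One-sided binomial test of n_meth against the error
rate: p = P(X >= n_meth | n, error). A site is an mC at p <= 1e-4 with
coverage >= 3. The coverage filter precedes testing: below-coverage
sites keep no p-value at all. The binomial-against-error-rate test is
the standard construction consistent with these p-value-plus-coverage
semantics.

**DMRs.** Disjoint 100-bp bins anchored at coordinate 0 ("100-bp bins"
with no step implies tiling). Within a context, a cytosine qualifies at
coverage >= 5; a bin is tested when both samples hold >= 3 qualifying
cytosines (the per-sample reading of the filter - stricter and
symmetric). Pooled bin levels are read-weighted (sum meth / sum total),
matching the count-based test. The per-bin test is two-sided Fisher's
exact on the pooled 2x2 table - the standard unreplicated-design test,
implemented directly. BH q-values are computed within
each context separately (contexts are thresholded and reported
independently). A DMR needs q <= 0.01 and |level difference| >= 0.25
(CG, CHG) or 0.15 (CHH); hyper means higher in stress.

**DEGs.** Pooled-variance two-sample t-test on log2(x+1) replicate
values, gated at p <= 0.05 and fold change >= 1.5 or <= 1/1.5, fold
change on replicate means with pseudo-count 1. At two replicates per
condition an unequal-variance (Welch) test loses essentially all power -
its Satterthwaite degrees of freedom collapse toward 1 (critical t ~
12.7) - while the generator draws equal variances by construction, so
the pooled test (df = 2) is the appropriate choice. Model-based
RNA-seq dispersion callers are out of scope at this scale; the gates,
which drive all set sizes, are preserved. Genotype-vs-genotype contrasts reuse the same
operation with different column pairing.

**Clustering and classes.** DEG-union k-means (k = 5, k-means++ with 100
restarts, fixed seed) on z-scored 4-group replicate-mean profiles.
Expression classes are quintiles of mean log2(x+1) with stable-order tie
breaks.

**Association and profiles.** A DMR joins a feature by its bin
mid-position: body if inside, promoter/upstream within 2 kb 5' of the
start (strand-aware), downstream within 2 kb 3' of the end; one record
per (DMR, feature) pair, so overlapping features yield multiple
associations. Metagene profiles use 40 length-proportional body bins
(this package's default, configurable) plus 2-kb flanks in 100-bp
bins, strand-oriented; density
is called mCs / covered cytosines (coverage >= 1) of the context, which
removes assembly-composition bias. Features shorter than 40 bp are
skipped and counted.

**smRNA/TE statistics.** Reads are collapsed to unique sequences with
multiplicities; a read joins a TE when its midpoint lies in the TE body
(mirroring the DMR midpoint rule); per-kb densities pool counts over a
set (sum counts / sum kb), which is the headline aggregate, with per-TE
densities feeding the two-sided Wilcoxon rank-sum comparison. The
rank-sum test enumerates all rank splits exactly (mid-ranks for ties)
when both groups have <= 12 observations and uses the tie-corrected
normal approximation otherwise. "smRNA-associated" is the binary >= 1
overlapping unique 24-nt (or 21-nt) read. TE-frequency enrichment uses
Fisher's exact test on harboring-gene counts; a gene harbors a TE when
the TE body overlaps the gene +/- 2 kb, and a TE is methylated when its
body contains >= 1 called mC.

## The synthetic study

The generator emulates the study design at desk scale so that every
downstream stage is testable by recovery; no external data is needed.
Defaults define the study conditions:

- **Genome**: 2 chromosomes x 1 Mb of i.i.d. uniform bases, plus a
  100-kb unmethylated control chromosome. 200 genes (1-5 kb, disjoint,
  slot-placed with 2-kb flank clearance) and 200 TEs (0.3-1.5 kb, 30%
  placed within gene +/- 2 kb windows, the rest intergenic, mutually
  disjoint).
- **Methylome**: a site mosaic - each cytosine is either methylated at a
  context-typical level or fully unmethylated. (fraction, level) pairs:
  background CG (0.30, 0.85), CHG (0.25, 0.75), CHH (0.01, 0.45); gene
  body CG fraction 0.20-0.80 scaled by the gene's expression rank (level
  0.85), CHG (0.05, 0.75), CHH (0.005, 0.45); TE body CG (0.45, 0.85),
  CHG (0.50, 0.75), CHH (0.55, 0.45). This reproduces the qualitative
  structure of plant methylomes: mC share CG > CHG > CHH, mean mC level
  CG > CHG > CHH, gene-body CG enrichment over flanks, TE-body density
  highest in CHH, and an expression-coupled gene-body CG gradient.
  Coverage is Poisson(30) per site per sample; methylated counts are
  Binomial(n, p + (1-p)*err) with conversion error 0.005; the control
  chromosome has p = 0 everywhere.
- **Planted DMRs** are aligned to the 100-bp grid and globally disjoint.
  60 background bins per context per direction set control/stress levels
  to (0.25, 0.65) for CG/CHG and (0.10, 0.35) for CHH - 0.40/0.25
  effects, chosen with headroom above the 0.25/0.15 gates so recovery
  failures indicate bugs, not power limits. 50 smRNA-target TEs gain
  CHH methylation at *new* sites under stress (+0.25 on non-CWA sites,
  +0.10 on CWA - the de novo, RdDM-like density gain) over every grid
  bin overlapping the body; 30 further "hyper-only" TEs gain *level* on
  their existing methylated mosaic (interior bins; density unchanged),
  modelling non-smRNA hypermethylation. This density-vs-level split is
  what makes the CWA/non-CWA comparison between associated and
  non-associated hypermethylated TEs informative.
- **Expression**: log-normal baselines (ln-mean 3, ln-sd 1, FPKM-like),
  two replicates per sample group with CV 0.1 noise; 20 planted DEGs per
  genotype (half up, half down) at fold change 3. Two replicates are
  generated although the emulated design is unreplicated, because the
  replacement t-test requires replication. Up-DEGs also receive one
  planted CHH-hyper promoter bin (the promoter-methylation/up-regulation
  coupling), and planted-DEG genes attract in-gene TEs with host weight
  40, creating the methylated-TE enrichment in dmDEGs.
- **smRNAs**: background 1 unique read/kb with a size distribution
  peaked at 24 nt (60%; 25% 21-nt); target TEs get 5x 24-nt/21-nt read
  density (x1.5 more under stress) and their 24-nt reads carry a 0.8
  C/T probability at each of the two 3'-terminal positions (the AGO4
  loading signature).
- A shared latent factor coupling per-gene CG and CHG stress shifts
  (loading 0.8) exists as an option but is off by default: leaving it on
  would plant real unrecorded differences that the DMR false-discovery
  accounting would count as errors. The correlation analysis is
  exercised under a dedicated coupled configuration in which the CHG
  gene-body methylated fraction is raised to 0.30, since the observable
  correlation of pooled level differences is attenuated by binomial
  counting noise when almost no CHG signal exists to shift.

All generator outputs are bit-identical given (config, seed); every
planted effect is recorded in a truth manifest sufficient for all
recovery metrics.

## What the synthetic data does and does not show

The generator has uniform base composition, no alignment artifacts, no
PCR duplicates, no M-bias, grid-aligned planted effects, and equal
variances across expression replicates. Passing recovery tests therefore
demonstrates that the statistical machinery is implemented correctly and
calibrated (null DMR calls <= the q threshold; Wilcoxon type-I in its
nominal band), not that the thresholds would achieve the same
sensitivity on real WGBS data, where effects are off-grid, coverage is
non-uniform and contexts interact.

## Numerical choices and degenerate inputs

Fisher p-values come from `scipy.stats.fisher_exact`, BH from
`statsmodels` (both verified in the tests against exact integer
enumeration and a brute-force step-up at 1e-10/1e-12). Kernel density
curves of DMR level differences fall back to a narrow Gaussian spike for
zero-variance inputs and are empty below 2 DMRs. Zero-coverage report
records are retained as density denominators but never tested.
Zero-variance vectors yield NaN correlations with a flag; empty strata in
the CWA split are flagged undefined rather than zero. Bins missing from
one sample are untestable by construction. K-means ties are resolved by
the fixed seed.

Two documented departures from conventional expectation: (1) the
permutation control for the expression-class trend uses the collapse of
the class-density range rather than a Spearman sign test, because with
five class-level points |rho| >= 0.5 occurs with probability 0.45 under
random ranks (54/120), making a sign criterion uninformative; (2) the
Welch-to-pooled t substitution described above.

## Problem sizes

The default study (2 x 1 Mb, ~1.05 M cytosines per sample, 4 samples)
is the scale at which the recovery analyses and the acceptance script
run; null calibrations run on 1 x 200-kb genomes (10 and 5 seeds), the
Wilcoxon type-I calibration on 200 re-simulated smRNA samples over a
150-kb genome, and the determinism check on a 1 x 300-kb genome. These
sizes were chosen so the whole suite exercises every stage at full
statistical fidelity while remaining a desk-scale computation.

## Known limitations

No replicate-aware dispersion modelling for methylation; no DMR merging
across adjacent bins; no smRNA target prediction or miRNA annotation;
single-threaded Fisher loop dominates DMR runtime on large genomes;
overlapping TEs are not supported by the interval-assignment fast paths
(the generator never produces them).
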