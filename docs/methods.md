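# Methods

## Study design and scope

The package analyses a crossed design: T taxa × S developmental stages ×
R biological replicates of bulk RNA-seq counts (default 4 × 4 × 4, the
layout of the pupfish craniofacial system it was built around, where each
replicate is a pool of sibling heads from a distinct parental pair). All
differential-expression comparisons are made *within* a stage, between
taxa; stages are never normalized against each other, because dissection
and tissue composition differ too much across stages for a shared scale
to be meaningful.

## Filtering and normalization

Genes flagged mitochondrial or pseudogene are removed first. Within a
stage, a gene is kept iff it reaches 1 cpm in ≥ ceil(n/2) samples or
2 cpm in ≥ ceil(n/4) samples, cpm computed on raw library sizes (the
filter runs before scaling factors exist, avoiding circularity). The
second prong deliberately retains genes expressed in only one taxon's
four replicates. Both cpm cut-offs and both fractions are parameters;
boundary behaviour is ≥ on both prongs.

TMM scaling factors follow the canonical formula: reference sample =
the one whose 75th-percentile count fraction is closest to the mean;
per sample, genes zero in either member of the pair are dropped, the
log2 ratio of count proportions (M) and average log abundance (A) are
rank-trimmed at 30% and 5% **per tail**, and the factor is 2 to the
weighted mean of surviving M with inverse delta-method variances as
weights; factors are rescaled to geometric mean 1. The implementation
is verified against an independently coded literal-formula oracle to
1e-10 and against the Bioconductor implementation to 1e-8. Note a
consequence of the definition worth stating: scaling a column's depth
by c moves its *library size*, not its TMM factor (M is computed on
proportions), so cpm is invariant — the factor only responds to
composition differences.

## Negative-binomial differential expression

Counts are NB with gene dispersion φ (variance μ + φμ²), log link, and
offsets log(effective library size) = log(N·f). Group rates are fitted
by Fisher scoring on the NB GLM score Σ(y−μ)/(1+φμ), vectorised across
genes.

**Common dispersion** maximizes the summed Cox–Reid adjusted profile
log-likelihood over genes (group means profiled out at each candidate
φ; the adjustment subtracts half the log Fisher information of each
fitted mean). Plain unadjusted profiling is biased low by roughly
(n−p)/n with few replicates — enough to visibly distort type-I error —
which is why the adjusted form is used for all dispersion estimation.
Likelihood-ratio statistics, by contrast, use the plain profile
likelihood at fixed φ.

**Tagwise dispersions** use weighted-likelihood moderation: each gene
maximizes its own adjusted profile log-likelihood plus an anchor curve
weighted by `prior_weight` prior degrees of freedom per residual degree
of freedom (default prior 10, the conventional moderation strength; on
a 16-sample/4-group stage that weights the anchor like ~0.8 genes'
worth of information). The anchor is, by default, the average
likelihood curve of the gene's abundance neighbourhood — 8 quantile
bins of mean log-expression — so shrinkage follows the mean–dispersion
trend; a scalar (untrended) anchor whose maximum sits exactly at the
common dispersion is available with `trend=False`, and in that mode an
infinite prior returns the common value to machine precision. The 1-D
maximization runs a vectorised golden-section refinement between the
bracketing nodes of a 25-point log-spaced grid spanning ±8 octaves
around the common value. The trended default matters: with a
φ = d0 + d1/μ trend, a scalar anchor drags well-expressed genes' φ̂ up
several-fold and halves discovery recall.

**Testing.** Each pairwise taxon contrast is an LRT of one shared rate
vs two group rates at the fixed tagwise φ, p from chi-square with 1 df.
log2FC is computed from prior-augmented normalized group means: a prior
count of 0.5, scaled per sample by relative effective library size, is
added so fold changes stay finite for all-zero groups; the same
augmentation defines the reported average log2 cpm. Swapping the groups
negates log2FC exactly and leaves p unchanged. FDR is Benjamini–
Hochberg (via statsmodels).

Calibration measured under a null simulation (φ = 0.1, 4 taxa × 4
reps, 5000 genes): the pooled fraction of p < 0.05 across the six
pairwise contrasts is ≈ 0.056 — slightly liberal, as expected for an
LRT with estimated moderated dispersions at n = 4 + 4, and inside the
0.035–0.065 band the test suite asserts.

## Discovery

The intersection set for a focal taxon at a stage holds genes with
FDR ≤ 0.1 and log2FC ≥ 0.2 (over) or ≤ −0.2 (under) in **all** pairwise
comparisons of the focal taxon against each other taxon, with the focal
taxon as numerator; genes whose sign differs between comparisons are
excluded. The |log2FC|-with-sign-consistency reading (rather than a
threshold on signed values only) is what makes the over/under split
well defined. Relaxing either threshold can only grow the set
(monotonicity is property-tested).

Across stages, the union of a focal taxon's stage sets is the
denominator for the multi-stage percentage (genes in sets at ≥ 2
stages). A multi-stage gene is *constitutive* when its mean log2FC over
the three comparisons keeps one strict sign at all stages — regardless
of per-stage significance. Genes lacking a mean log2FC at some stage
(filtered out there) stay multi-stage but are excluded from the
constitutive subset and reported in a diagnostics list; a mean log2FC
of exactly 0 at any stage also blocks the constitutive flag.

## Enrichment

*Curated-list overrepresentation.* The observed overlap between a query
list and a curated list is compared with the overlap of `n_perm`
(default 1000) random same-size draws from the analysis universe.
The empirical p uses the (1 + exceedances)/(1 + n_perm) correction so
Monte-Carlo p-values are valid (never zero). Because the null is
exactly hypergeometric, the closed-form upper tail is reported next to
the empirical value; the test suite checks their agreement to within
Monte-Carlo error.

*Pre-ranked GSEA, classic scheme.* Ranked lists are ordered by
descending score with ties broken by gene identifier. Walking the list,
a set member adds 1/G and a non-member subtracts 1/(N−G); ES is the
running-sum value of maximum absolute deviation (first such position on
exact ties). The observed ES uses the full cumulative sum; the null —
random same-size gene draws, the standard null for a pre-ranked list —
uses a closed-form evaluation at the sorted hit positions that is
algebraically identical and differs only at float-tie knife edges. In
exhaustive mode (small C(N,G)) the null is enumerated through the same
cumulative-sum path as the observed score, so nominal p equals the
exact same-sign tail fraction. NES divides ES by the mean |null ES| of
matching sign; nominal p is the matching-sign tail (with the +1
correction in Monte-Carlo mode); the FDR q compares the fraction of
pooled sign-matched null NES beyond each observed NES with the fraction
of observed NES beyond it, clipped at 1. The q formula is one of
several variants in circulation and is documented here rather than
asserted to match any external program's output. Set members absent
from the ranked list are dropped with a logged count; sets with no
member present, or spanning the entire list, are skipped with a
warning.

## Ordination

Expression enters as log2(cpm + 1) on TMM-effective library sizes; cpm
is used instead of length-normalised units because gene length is
constant within a gene and cancels in between-sample ordination. Genes
are centered but not variance-scaled. PCA is by SVD (via
scikit-learn, full solver); variance fractions are singular values
squared over their full-rank total; each component's sign is fixed so
its largest-|loading| gene is positive, making loading-based rankings
reproducible. Requested components beyond the matrix rank are truncated
with a warning.

## Coverage intervals and supermatrix

Coordinates are 0-based half-open throughout (bedGraph convention);
FASTA output is sequence-only. The joint catalog holds maximal runs
where every sample's depth ≥ 10 at every base — by construction the
supermatrix has no missing data. Length bounds default to the strict
window 51 ≤ length ≤ 999 bp (both bounds configurable, since "between
50 bp and 1 kb" and "longer than 50 bp and less than 1 kb" differ at
the boundary and the choice cannot be recovered; the stricter reading
is the default). Consensus slices are concatenated in catalog order;
the coordinate map records each interval's supermatrix column range for
downstream partitioning. Intervals containing N in any sample are
reported, and dropped in strict mode. Tree inference itself is out of
scope; the supermatrix and map are exported for external tools.

## Synthetic data generator

The generator is the package's test bed and defines its study
conditions:

* Gene mean cpm is lognormal (natural-log mean 3.0, sd 1.8 — median
  ≈ 20 cpm, and the implied mean of ≈ 100 cpm makes 10⁴ genes sum to
  ≈ 10⁶, keeping the cpm scale self-consistent).
* Dispersion follows φ = d0 + d1/μ with d0 = 0.02 and d1 = 2.0: a 14%
  biological-CV floor — appropriate for replicates that are pools of
  many siblings, each pool from a different parental pair — rising
  steeply at low expression. The within-taxon variance components are
  not identifiable from published summaries, so these defaults are the
  package's own stated choice.
* Library sizes are uniform on [15, 20] million reads and fixed before
  count drawing (1 cpm ≈ 15–20 reads), so normalization is exercised
  without confounding the planted truth.
* Effects are planted as focal-taxon-vs-rest shifts of ±`effect_size_log2`
  (default 0.4 ≈ 1.3-fold, typical of between-taxon divergence in
  closely related species; recovery benchmarks use 1.0). Per focal
  taxon, a disjoint pool of `de_fraction` × n_genes genes receives
  effects at every stage: a `constitutive_fraction` of them with one
  sign throughout, the rest with per-stage random signs forced to flip
  at least once, so the constitutive classifier has decidable truth.
* Counts are gamma–Poisson draws; a master seed is split into named
  substreams (gene parameters, planted effects, library sizes, counts),
  so identical config + seed reproduces byte-identical output.
* The coverage fixture plants Poisson depth with forced low-coverage
  gaps and per-sample substitutions on a shared random reference; its
  truth catalog is the joint-coverage scan at depth 10.

What the generator does **not** emulate: mapping and counting artefacts,
GC/length biases, correlated gene modules, batch structure, or
compositional shifts between stages. Passing tests therefore demonstrate
correctness of the inference machinery under the stated NB model, not
robustness to those real-data phenomena.

## Benchmark problem sizes

The acceptance suite measures: type-I calibration on 5000 genes × 16
samples (six pooled contrasts); discovery recall/FDP on 4000 genes with
10% planted at |log2FC| = 1 (recall computed over planted genes with
mean cpm ≥ 50, where the design has power; observed ≈ 0.94 recall at
≈ 0.02 FDP); log2FC bias over ≈ 2100 well-expressed planted genes
(|bias| < 0.01); permutation-vs-hypergeometric agreement over 50
scenarios at 10⁴ permutations; GSEA ES equality with a brute-force
oracle on 200 instances and exhaustive-null p on N = 12, G = 3; TMM
oracle agreement to 1e-10; a 12-gene constitutive enumeration; 100
random interval fixtures against a per-base scan; PCA variance and
silhouette checks; and a full default-size (10⁴ genes) pipeline run
executed twice to confirm byte-identical manifests. These sizes were
chosen to give stable measurements at interactive runtimes.

## Known limitations

* Single-factor contrasts only: no batch covariates, no multi-factor
  GLMs, no quasi-likelihood dispersion uncertainty — p-values are mildly
  liberal at n = 4 per group.
* The GSEA FDR q variant is documented, not calibrated against external
  software.
* TMM assumes most genes are not differentially expressed between the
  pair being compared; severe global shifts violate it.
* The constitutive classifier conditions on intersection-set membership
  at ≥ 2 stages, so it undercounts genes with persistent but
  sub-threshold differential expression.
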