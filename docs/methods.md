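# Methods

## Scope and data model

The pipeline consumes per-cytosine methylation evidence (a 7-column,
Bismark-CX-style TSV: chromosome, 1-based position, strand, methylated
count, unmethylated count, context, trinucleotide), interval annotations
(genes and TEs with family/superfamily labels), external region sets
(BED), and nonnegative expression matrices. It does not touch reads:
trimming, alignment, duplicate removal and methylation extraction are
upstream concerns, as is read-level M-bias handling.

Contexts are classified from the trinucleotide starting at the cytosine,
read 5'→3' on the cytosine's own strand: CG if the second base is G, CHG
if the second base is A/C/T and the third is G, CHH if both are A/C/T.
A cytosine whose 3-mer runs off the chromosome end or contains a non-ACGT
base has no context and is skipped. The context column of a report is
advisory; the trinucleotide is authoritative, and disagreements are
repaired with a warning. Chromosome names are matched exactly — no
"chr"-prefix normalization, because silent renaming moves coordinates
between genomes without anyone noticing.

Coordinate conventions: cytosine reports 1-based; BED 0-based half-open;
GFF3 1-based inclusive, converted to 0-based half-open on load. All
internal interval arithmetic is 0-based half-open, and a 1-based cytosine
at position p lies in region [start, end) iff start < p ≤ end.

## Methylation levels

Every summary (global, per-window, per-region, per-feature, per-metaplot
bin) is the *weighted* level: total methylated counts over total counts.
Means of per-site ratios are never used — they weight a 1× site equally
with a 50× site and are badly behaved at low coverage. A set with zero
covered reads has an *undefined* level (NaN), which is distinct from 0.

The bisulfite conversion rate is estimated on a control contig assumed
fully unmethylated (the chloroplast in plant WGBS; the `plastid` contig
in the synthetic genome): rate = Σ unmethylated / Σ total. It is reported
as QC only and is not used to correct levels by default; an explicit
correction `level' = max(0, (level − f) / (1 − f))` with failure rate
`f = 1 − rate` is available (`correct_level`) for users who want it.

Replicates with the same stage and fraction are pooled by summing counts
per (chromosome, position, strand), which makes pooling exactly
associative with the weighted level.

Chromosome tracks tile each chromosome from 0 with a fixed window and
step (default 100 kb / 100 kb; the window size for genome-scale
visualization is a display choice, exposed as a parameter). Empty windows
are reported as undefined, not zero.

## DMP calling and DMR clustering

For each cytosine of the chosen context covered by at least `min_cov`
reads in both samples (default 4), the 2×2 table
(meth_a, unmeth_a; meth_b, unmeth_b) is tested with a two-sided Fisher's
exact test: the p-value is the sum of hypergeometric probabilities of all
tables with the observed margins whose probability does not exceed the
observed table's. The implementation compares exact integer weights
C(r1, k)·C(r2, c1−k) (rational-safe; no floating-point ties) for totals
up to 10,000 and falls back to floating hypergeometric pmfs with a 1e-12
relative tolerance beyond that. Results are cached per table, which makes
genome-scale calling cheap because coverage-limited tables repeat.

Significance defaults to raw p < 0.01 with no multiple-testing
correction; Benjamini–Hochberg is available (`mtc="BH"`). For CG, the two
strands of a dyad are summed before testing by default (CG methylation is
symmetrically maintained; this halves the number of tests and doubles the
per-test coverage). CHG/CHH are tested per strand.

DMPs sorted by position are clustered in one linear pass: a DMP joins the
current cluster iff its distance to the previous DMP is ≤ 50 bp (strictly
greater splits). Clusters with fewer than `min_dmps` (default 2) members
are dropped. A DMR spans [min_pos − 1, max_pos) so a single-DMP region
covers 1 bp. `score_dmrs` attaches the weighted-level difference over the
region; `evaluate_against_truth` scores called regions against planted
truth by interval Jaccard.

### Known limitation: fragmentation of 50-bp clustering

Region recovery by this procedure is limited by two compounding factors.
First, per-site power: at 20× coverage a 0.4 shift on a low background
reaches only ~0.65 probability of p < 0.01 under the (conservative,
discrete) Fisher test. Second, site spacing: CHG sites on an AT-rich
(~36% GC) sequence occur at ~0.05/bp, so stretches longer than 50 bp
without *any* significant site occur several times inside a typical
300–800 bp region. Each such stretch splits the region's called DMR into
fragments. Consequently single called DMRs usually cover well under half
of a planted region even when every inside cytosine is detected, and
region-level precision/recall at Jaccard ≥ 0.5 stays low (~0.02/0.08 at
defaults; still ~0.2/0.6 under deliberately favorable GC-rich sequence
and looser alpha). This is a property of per-cytosine testing plus
fixed-gap clustering at moderate coverage, not of the implementation; the
set-level permutation z-score (below) detects the same planted signal at
z ≈ 30 under identical conditions. Users wanting region-accurate
boundaries need higher coverage, pooled dyad/neighborhood tests, or
window-based callers, all outside this package's procedure.

## Permutation z-score enrichment

Given an external region set (e.g. hypo/hyper DMRs of a silencing-pathway
mutant), the observed statistic is the mean per-cytosine difference in
level (sample b − sample a) over all context cytosines inside any region,
covered ≥ `min_cov` in both samples. The mean of per-cytosine differences
is used rather than the difference of pooled levels (the pooled variant
reflects the same signal but weights regions by coverage; the
per-cytosine mean matches the statistic's description as "differential
methylation for cytosines overlapping" the set).

The null is built from region *sets* matched to the template: each of
`n_perm` (default 1,000; tests use 200) permuted sets copies the
template's region count and lengths, placing each region uniformly — the
chromosome is drawn with probability proportional to its length among
chromosomes long enough, the start uniformly such that the region fits.
Placement ignores TE overlap deliberately and excludes the control
contig. One aggregate statistic per permuted set makes observed and
permuted values commensurable, and
`z = (observed − mean_perm) / sd_perm` with the sample sd (ddof 1).
Permuted sets with no qualifying cytosines are dropped; more than half
undefined raises. `z` is NaN when the permutation sd is zero (e.g. a
sample contrasted with itself). Under null simulations z is approximately
standard normal (100 seeded replicates: |mean| < 0.1, sd ≈ 0.8), so |z|
≥ 3 is a conservative signal threshold. Swapping the two samples negates
the statistic and z exactly for a fixed seed.

The enrichment matrix evaluates every (region set × stage contrast ×
context) cell with an independent, deterministically derived seed
(crc32 of the base seed and cell labels), so any cell can be reproduced
standalone; per-cell failures become NaN without aborting the matrix.

## Region-level PCA

A region × sample matrix of weighted levels is assembled for a region set
(typically CHH regions at TEs); a region is kept only if it carries at
least `min_cov` reads in *every* sample — no imputation. PCA is the SVD
of the feature-centered matrix (feature means removed; no variance
scaling, since all entries share the [0, 1] level scale). Sample
coordinates are the projections; explained-variance fractions are
normalized squared singular values. Coordinates are defined up to
per-axis sign. Convergence of samples toward a reference (e.g. stem cells
approaching a meiocyte-like methylome with age) is quantified as
Euclidean distance in the first two PCs.

## Profiles

Metaplots aggregate counts into 2 kb flanks (20 bins of 100 bp) and a
fractional body (40 bins), oriented 5'→3' per feature; minus-strand
features contribute their genomic bins in reversed order, which makes the
minus-strand profile the exact mirror of the plus-strand one. Bins pool
counts across all features before forming a level, so short or
low-coverage features do not dominate; a cytosine under two overlapping
features counts toward both (no deduplication). Flank bins never absorb
body cytosines: the upstream panel is exactly [start − flank, start).

The level-versus-length trend for TEs is fitted with LOWESS (tricube
local linear regression, span 0.3, two bisquare robustifying iterations,
via statsmodels); features with undefined levels are dropped and at least
10 defined points are required. Constant input is reproduced exactly and
a globally linear trend is recovered at interior points to numerical
precision.

## TE expression summaries

The module consumes an abundance matrix (TPM-like) with paired stem/
non-stem columns per stage. Differential-expression significance is
deliberately not recomputed — that belongs to count-based tools upstream;
what is computed here: log2((stem + 1) / (nonstem + 1)) per feature
(pseudocount 1, configurable), family aggregation by summing members
(exactly conserving per-sample TE totals; unlabeled TEs go to "Unknown"
with a warning), per-stage counts of families with |log2fc| ≥ 1 (the
boundary counts), and two-sided unpaired Wilcoxon rank-sum tests between
feature classes (exact enumeration when the pooled sample size is ≤ 20
without ties, otherwise the normal approximation with tie and continuity
corrections). For log-scale display of zero-containing values the
transform log10(x + 1e-6) is provided — the offset convention of adding a
value a factor 10 below the smallest observed non-zero measurement.

## Synthetic data: what it emulates and what it does not

The generator exists so every statistical claim above can be tested
against known truth. It produces:

- a genome of `n_chrom` chromosomes (default 2 × 200 kb) of AT-rich
  random sequence (32/18/18/32% A/C/G/T, Arabidopsis-like GC) plus a
  10 kb unmethylated control contig;
- TEs whose midpoints follow a triangular density peaked at the
  chromosome midpoint (the "centromere"), mixing <2.5 kb and >2.5 kb
  length classes, with family/superfamily labels drawn from a pool of
  `n_te/2` (≤ 20) families; genes placed uniformly; features never
  overlap, and infeasible packing raises rather than silently crowding;
- true per-cytosine methylation probabilities: means per (feature kind ×
  context) — defaults TE 0.85/0.35/0.10 and gene body 0.20/0.02/0.02 for
  CG/CHG/CHH over a 0.05/0.02/0.02 background — with beta-distributed
  site-to-site variation (concentration 50; `None` disables it);
- planted DMRs: non-overlapping regions whose target-context cytosines
  are shifted by a signed delta (clipped to [0, 1]) in a second
  methylome, with the truth set returned for evaluation (defaults: 50
  CHG regions of 300–800 bp, delta +0.4 in the stem fraction);
- observed counts: per cytosine, coverage n ~ Poisson(mean; default 20×)
  and n_meth ~ Binomial(n, p + (1 − p)·f) with conversion-failure rate
  f = 0.005, i.e. a 99.5% conversion rate, within the range typical of
  plant WGBS controls. Failures inflate apparent methylation — the
  direction a chloroplast control measures; non-conversion of methylated
  cytosines is ignored;
- expression matrices: per-feature log-normal base abundances, a shared
  per-stage developmental factor for non-housekeeping features (so the
  stem/non-stem ratio is unaffected), planted family activation
  (default 12 families × fold 4 in the D7 stem column), constant-mean
  housekeeping features, and multiplicative log-normal noise
  (CV 0.2, mean-one).

All generators are deterministic under a fixed seed; the bundled
`simulate_study`/`stemmeth simulate` chain derives all sub-seeds from one
master seed, and repeated runs are byte-identical.

Deliberately not modeled: reads (PCR duplicates, mapping bias, M-bias),
single-nucleus sparsity, realistic sequence motifs (TE bodies are random
sequence, so context density is composition-driven), chromosome-scale
methylation gradients beyond the TE/gene/background partition, and
count-based expression noise (the matrix is TPM-like, not counts). A
passing test suite therefore demonstrates the *statistical* correctness
of the procedures under the stated sampling models — it does not
establish performance on real libraries, where coverage heterogeneity
and sequence composition can be less favorable.

Problem sizes in the test suite (2 × 100–200 kb genomes, 20–30× coverage,
100 null replicates at 200 permutations) were chosen as the smallest
sizes at which the checked distributional properties are stable.

## Numerical choices and degenerate inputs

- Fisher: exact integer comparison of hypergeometric weights; p of an
  empty table is 1.
- z-score: sample sd (ddof 1); sd 0 → z NaN; >50% undefined permutations
  → error.
- PCA: constant matrix → all-zero coordinates and variance fractions;
  fewer than 2 samples or 3 surviving regions → error.
- Levels: empty denominators are NaN everywhere, never 0; windows/bins
  report their cytosine and read counts so callers can filter.
- Clustering: input must be position-sorted (checked); output is
  invariant to chromosome processing order.
- LOWESS: span outside (0, 1] → error; output bounded by the input range.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; library functions never consume global random state.
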