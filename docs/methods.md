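# Methods

This note documents the statistical model, the numerical choices, what the
synthetic-data generator does and does not emulate, and the design decisions
taken where the design was genuinely open.

## The overlap-enrichment model

A trait is summarized by its *element set* E: the deduplicated genes
obtained by mapping each independent genome-wide significant variant to the
closest gene of an allowed biotype within `dist_bp` (default 5,000 bp) of
the variant.  The biotype whitelist defaults to the 15 Ensembl/VEP
protein-coding-family biotypes (protein_coding, the IG_*/TR_* gene
segments, nonsense_mediated_decay, nontranslating_CDS, non_stop_decay,
polymorphic_pseudogene); it is user-overridable.  Distance is 0 for a
variant inside the gene body and otherwise the 1-based separation to the
nearest included gene base; the window is inclusive at `dist_bp`.  Ties
(two candidates at equal distance) break deterministically by smaller start
coordinate, then lexicographic feature id.  Element sets smaller than
`min_set_size` (default 50; 40 is retained as a documented preset for
reporting contexts) are excluded as underpowered.

The test statistic is intersections per base pair,
`T = overlap_count / total_bp(E)`, where by default each element counts at
most once regardless of how many annotation intervals it touches
(`count_mode="unique"`); pair counting is available for sensitivity checks.

## The length-matched null and the Weibull tail

Gene lengths are heavy-tailed, and longer intervals are more likely to
touch any annotation, so the null must match the element set's length
profile.  Elements are sorted by length and split into 10 contiguous
index-bins (bin k covers sorted indices floor(kN/10)..floor((k+1)N/10)-1,
so bin sizes differ by at most one; ties stay in sorted order).  Each of
`n_reps` (default 1,000) replicates places, for every bin, n_k intervals of
the bin's integer-rounded mean length uniformly on the genome: chromosome
sampled with probability proportional to (chrom_length − l + 1), start
uniform over the valid range.  Background intervals may overlap each other
and real genes; no masking is applied.

A two-parameter Weibull (no location shift) is fitted to the replicate
statistics by maximum likelihood (`scipy.stats.weibull_min.fit` with the
location fixed at 0); the reported p-value is the fitted upper tail
`exp(-(t_obs/lambda)^k)`.  Zero-valued replicates are excluded from the MLE
(the Weibull support is x > 0).  If more than half the replicates are zero,
or the positive values are constant (e.g. an annotation covering the whole
genome), the fit is skipped and the empirical rank p-value
`(1 + #{T_i >= t_obs}) / (n_reps + 1)` is used; the condition is recorded in
the result's `fit_note`.  Enrichment is
`I = (t_obs − mean(T_null)) / mean(T_null) × 100%`; the per-bp statistic is
primary and a raw-count variant is reported alongside (the two differ only
through the small mismatch between the element set's total bp and the
binned background's total bp).  BH-FDR is applied across all rows of an
invocation by default (`fdr_family="batch"`); per-annotation families are
available.

The mapping distance convention deserves one note: conventions differ by
±1 bp at interval edges across tools.  We use the 1-based separation to the
nearest included base (a gene whose body starts exactly 5,000 bp from the
variant is accepted at the default window) and apply it identically on both
sides of the gene.

## Concordance between two methods

Two results tables (e.g. gene-overlap enrichment vs heritability
enrichment) are each converted to within-table ranks of their enrichment
values, joined on (trait, annotation), and compared by a two-sided Wilcoxon
signed-rank test on the paired rank differences (zeros dropped, mid-ranks
for ties, exact null for ≤ 25 nonzero tie-free differences, normal
approximation with continuity correction otherwise).  Two properties of
this procedure are worth stating plainly, because they shape what a
non-significant result means.  Paired rank differences always sum to zero,
and for *any* two independent rankings they are near-symmetric about zero —
so the test is conservative: it rejects only for asymmetric rank shifts
(a few traits moving far against the grain), not for mere disagreement.
In particular a perfectly reversed ranking yields exactly symmetric
differences (W+ = W−) and p = 1.  A large p therefore means "no detectable
asymmetric displacement between the rankings", not "the rankings agree".

## Correlated random-effects meta-analysis

Per-trait estimates y with standard errors s within a category are modeled
as y = mu·1 + u + eps with Cov(u) = tau²·I and Cov(eps) = diag(s)·R·diag(s),
where R is the trait-trait (genetic) correlation matrix.  tau² is estimated
by REML via a bounded 1-D profile search on [0, 10·var(y)] (the boundary
tau² = 0 is preferred when its restricted likelihood is at least as good);
mu by GLS given tau², with se(mu) = (1ᵀV⁻¹1)^(−1/2).  The placement of R in
the sampling covariance (rather than on the random effect) is a modeling
choice, since the source procedure is stated only as "considering" the
correlation matrix; the alternative Cov structure tau²·R is available via
`structure="tau2R"`.  Against R metafor's `rma.mv` (REML, random intercept,
V = diag(s)·R·diag(s)) the implementation agrees to ~1e-7 on the frozen
test fixture.  Non-PSD correlation inputs are repaired by clipping
eigenvalues at 1e-8 and rescaling to unit diagonal; an exact identity
matrix passes through untouched.  With R = I and tau² = 0 the estimator
reduces exactly to the inverse-variance weighted mean.

## Perturbation harness

Robustness of conclusions to annotation boundary error is probed three
ways: keep a random 90% of regions (3 replicates), or move every region's
two ends inward/outward by 5% of that region's own length (rounded half-up,
clamped to chromosome bounds, never shrinking below 1 bp) — making each
region about 10% shorter or longer.  Backgrounds are re-run with the *same*
per-trait seeds as the original analysis so the reported Pearson
correlations (enrichment and −log10 p vectors across traits) reflect the
annotation change only.  Because shrink acts on the already-extended
length, extend-then-shrink is not an exact inverse: it compounds by about
2·(0.05)²·L per region plus rounding.

## Synthetic data: what it emulates and what it does not

The generator produces a desk-scale genome (default 2 × 10 Mb), 2,000 genes
with log-normal lengths (median 2 kb, sigma 0.5; 70% protein-coding),
a merged annotation assembled from log-normal regions (median 1.5 kb) until
it covers 5% of the genome (realized coverage within 2% of target; the last
regions are trimmed on overshoot), and 60 significant loci per trait.
Defaults were chosen once as realistic desk-scale analogs of a GWAS trait
(tens of independent loci, annotations covering a few percent of the
genome) and a full study runs in seconds on one CPU.

Planted enrichment rho acts at the gene level, matching the statistic being
tested: each hit's gene is, with probability rho, drawn from the genes
overlapping the annotation, else uniformly from all whitelisted genes.
Planted variants are placed inside the gene's intersection with the
annotation, so at rho = 1 every mapped element overlaps the annotation even
if a distance-0 tie swaps the mapped gene; non-planted variants are placed
uniformly in the gene ± dist_bp/2.

In calibration studies every synthetic trait redraws its gene table on the
shared genome and annotation.  This matters: with one fixed gene table, all
traits share that table's realized overlap offset (the fraction of its
genes touching the annotation deviates from expectation by placement
noise), and measured type-I error would characterize the single gene-table
draw rather than the method.  With independent redraws the pipeline's null
p-values are uniform and the 5% test rejects at close to 5%.

The generator does **not** emulate LD structure, allele frequencies, minor
allele count thresholds, effect-size architecture, gene clustering, GC
content, or assembly gaps.  Passing tests therefore demonstrate the
correctness and calibration of the enrichment machinery under its stated
sampling assumptions — not that real GWAS loci meet those assumptions
(in particular, LD-clumping quality and non-uniform gene placement are
upstream concerns the pipeline inherits).

## Numerical and determinism choices

All coordinates are 0-based half-open internally; 1-based inputs (gene
tables, variant positions) convert at the parser boundary.  Book-ended
intervals merge.  Chromosomes sort naturally (chr1 < chr2 < chr10).
Strand is ignored.  All randomness flows from a single integer seed through
`numpy.random.SeedSequence` derivations; reruns with the same inputs and
seed are byte-identical (results tables use fixed 6-decimal formatting,
which rounds extremely small p-values to 0.000000 — the JSON sidecar and
API keep full precision).  Backgrounds for one trait are drawn vectorized
from one generator rather than per-replicate substreams; determinism under
the configured seed is the tested contract.

## Known limitations

- The Weibull tail is an approximation to a discretized (count-valued)
  statistic; with small element sets and tiny annotations its tail can be
  conservative.  The empirical-rank fallback bounds p away from 0 at
  1/(n_reps + 1).
- The background samples random genomic intervals, not random genes;
  gene-resampling is a possible alternative null universe that would
  condition on gene placement.
- `overlap_proportion` requires merged inputs by contract; unmerged inputs
  raise rather than silently double-counting.
- The concordance test's conservatism (above) means it is best read as a
  check against gross asymmetric disagreement, not as evidence of
  agreement.
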