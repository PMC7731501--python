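# Methods

This note documents the statistical models behind `hybridexpr`, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the design choices made where the design was open.

## Normalization

TMM treats one sample as reference (the sample whose depth-scaled 75th
percentile is closest to the across-sample mean) and, for every other
sample, computes M-values (depth-adjusted log2 expression ratios) and
A-values (average log2 abundance) over transcripts positive in both
members of the pair.  The top and bottom 30% of M-values and 5% of
A-values are trimmed; the factor is 2 to the weighted mean of the
surviving M-values with inverse delta-method variance weights
1/v, v = (N_o − o)/(N_o·o) + (N_r − r)/(N_r·r).  Factors are rescaled
to geometric mean 1.  The implementation reproduces the Bioconductor
reference implementation to ~1e-10 (cross-checked in the test suite via
`Rscript`).

One subtlety the tests document: because the weights contain the
observed sample's library size, multiplying a column by a constant c
rescales that sample's variance term by 1/c non-uniformly across
transcripts, so the factor is *exactly* depth-invariant only as the
M-value dispersion goes to zero.  On deep counts over a shared profile
the deviation is ~1e-7; on noisy independent columns it can reach 1e-3.
This is a property of the published weighted algorithm, not of this
implementation.

FPKM is computed against effective (TMM-scaled) library sizes:
count × 10⁹ / (length_bp × effective size).  Log expression is
log2(FPKM + 1); the pseudocount (default 1) and per-transcript row
centering are configurable — heatmap-style displays center per
transcript, model responses do not.

## Differential expression

Counts are modeled NB with variance μ + φμ² (edgeR-style dispersion φ).
A single common φ is estimated by maximizing the conditional ("given
the group total") log-likelihood summed over transcripts, after an
expectation-matching rescale of every sample to the geometric-mean
effective library size (rounded to integers).  The optimizer is a
bounded golden-section search on [1e-6, 10] with tolerance 1e-4.
Common dispersion (no tagwise empirical-Bayes shrinkage) is a
deliberate simplification: it keeps every p-value exactly checkable
against an enumeration oracle, and the downstream gates (q ≤ 0.001,
|log2FC| ≥ 5) are far from the regime where tagwise shrinkage changes
calls.

The exact test conditions on the total s of the two group sums; the
conditional distribution of the split is negative hypergeometric with
shape parameters n_A/φ and n_B/φ (binomial when φ = 0).  The two-sided
p-value is the total probability of splits whose probability does not
exceed the observed one ("minimum likelihood"; a tail-doubling variant
is available).  The pmf is normalized in log space, ties are matched
with a 1e-10 log tolerance, and the p-value is exactly 1 when the
observed split is the conditional mode.

Fold changes are log2 of the ratio of per-replicate group means of the
rescaled counts, with a 0.5 pseudocount on each group sum so that
all-zero groups stay finite.  "Expressed" means a raw total of at least
`min_total_count` (default 10) across the two groups, so each
comparison has its own expressed universe, as in published per-
comparison "all transcripts" totals.  Multiple testing uses
Benjamini–Hochberg (via statsmodels).  The default fold-change gate of
2⁵ is kept as printed in the motivating study, and is configurable —
it is unusually stringent, and combined with the FDR gate it makes
false DET calls essentially impossible on null data.

## Inheritance modes

With outcomes of the three pairwise tests (A–B, A–H, B–H), each
transcript expressed in all three comparisons gets exactly one mode:

| mode              | rule                                                      |
|-------------------|-----------------------------------------------------------|
| conserved         | no comparison significant                                 |
| transgressive up  | H significantly above both parents                        |
| transgressive down| H significantly below both parents                        |
| additive          | H significantly above one parent, below the other         |
| dominantA / B     | H indistinguishable from that parent, different from other|
| ambiguous         | parents differ but H matches both                         |

Significance is the DET call (both gates), since classification in the
motivating design operates on DET output.  The `ambiguous` bucket is
kept explicit rather than silently merged so mode counts always sum to
the classified total; it is exactly the "parents differ, hybrid matches
both" pattern, which a three-way design cannot attribute.  The decision
table is closed: the test suite enumerates all 27 internally consistent
outcome triples against an independently written oracle.

## Soil ordination and the environmental predictor

The soil panel is fixed to 14 variables (pH, OM, CEC, SB, BSP, ASP, PA,
P, K, Ca, Na, S, Al, Mg).  PCA standardizes columns (correlation-matrix
PCA) and the gradient predictor is PC1.  Sign conventions matter for
reproducibility: every component is oriented so its Na loading is
non-negative (sodium increases toward the wet/saline end of the
gradient, so PC1 scores increase in that direction).  LDA solves the
generalized eigenproblem on between- and pooled within-group scatter;
when the within matrix is singular (more variables than sites is
normal for soil panels) it is ridge-regularized by 1e-8·trace/dim.
Coefficients are scaled to unit pooled within-group variance, the
convention used for published linear-discriminant coefficient tables.

## Latent factor mixed model and calibration

The association model is Y = UVᵀ + XBᵀ + E with Y the (samples ×
transcripts) log2(FPKM+1) of DET transcripts, X the PC1 predictor
(centered, unit variance), U the K latent confounder axes, and ridge
penalty λ on B.  Defaults: K = 2 (set a priori, as in the motivating
design; a scree of PCA variance fractions can inform the choice but is
never auto-applied), λ = 1e-5 (the published ridge-LFMM default).

Profiling B out of the objective leaves a weighted-Frobenius rank-K
problem whose global minimizer is closed-form: shrink each predictor
direction q_i of the data by √(λ/(σ_i² + λ)), take the rank-K truncated
SVD, and map back.  The solver seeds the block-coordinate loop — (U,V)
from the truncated SVD of Y − XBᵀ, then B by per-transcript ridge —
at that analytic optimum; each block step is an exact minimization, so
the objective trace is non-increasing by construction (asserted every
iteration), and the seed avoids the extremely slow zigzag a cold start
exhibits when the predictor correlates with the low-rank structure.
On random 8×30 instances the final objective matches a 20-restart
L-BFGS oracle to ~1e-13.

Test statistics are per-transcript OLS of y on [1, X, U] with the
normal approximation to the predictor's t-statistic.  Because U is
estimated from Y itself, null z-scores are miscalibrated whenever the
confounders correlate with the predictor; the genomic inflation factor
λ_GIF = median(z²)/0.4549364 (the χ²₁ median, fixed to 7 digits)
rescales z² before the χ²₁ tail probability.  GIF is a scale-only
correction: it repairs the null under moderate-to-strong confounding
(the regime exercised in the tests) but cannot fix arbitrary shape
distortion under extreme confounding — a known limitation.  Significant
association means calibrated p < 0.05, as printed in the motivating
design; BH on calibrated p is available as an option.

## GO enrichment and redundancy reduction

Annotations follow the true-path rule (a gene on a term is on all its
ancestors); term information content is IC = −log(n_term/n_root) over
the propagated corpus — self-contained, with no external annotation
database.  Gene scores are p-value-like (smaller = more interesting);
the KS variant is used because scores are continuous, unlike
Fisher-style count tests.  Each term is tested one-sided (two-sample
exact KS via scipy, term scores stochastically smaller) against all
other scored genes.  The elim walk processes terms by decreasing depth
(longest path from the root); a term below `elim_cutoff` (default 0.01,
the conventional tool default; the reporting threshold is 0.05) has its
currently retained genes removed from all ancestors before they are
tested, so ancestors must carry signal beyond their significant
descendants.  Terms with fewer than `min_genes` = 5 retained genes are
skipped to avoid degenerate KS tests.

Redundancy reduction uses Lin similarity 2·IC(MICA)/(IC₁+IC₂) with the
maximum-IC common ancestor (terms count as their own ancestors); Lin is
chosen among the REVIGO family because it is self-normalizing to [0,1].
A greedy sweep in ascending p (ties: larger IC, then term id) keeps a
term iff its similarity to every kept term is ≤ 0.5, giving a
deterministic representative set.

## Synthetic data

The generator emulates a three-group hybrid-zone design: two parental
species and hybrids with `replicates_per_group` (default 4, matching
the few-individuals-per-taxon-per-site scale of field sampling)
biological replicates each.  Per transcript, baseline expression is
log-normal (median `base_mean` = 100 expected counts, spread
`base_log_sd` = 1 natural-log unit — a typical bulk RNA-seq abundance
spread); group offsets implement the planted mode (±effect_log2fc as
half-offsets for dominance, full offsets for transgression, 2× between
parents for additive so the hybrid sits midway); library sizes are
log-uniform on (5e5, 2e6) and enter as mean multipliers; counts are NB
with dispersion 0.2 (0.1 in the low-noise scenarios), the scale of
biological variation between conspecific individuals.  Latent
confounders are standard-normal sample scores with N(0, latent_sd)
loadings on the natural-log scale; the first confounder is planted at
an exact sample correlation (`latent_env_corr`, default 0.5) with the
environmental predictor — confounding aligned with the gradient is
precisely the situation the LFMM exists to handle, and planting the
correlation exactly makes "confounding strength" a controlled condition
rather than a random draw.  The environmental predictor is uniform on
[−1, 1] per sample (a dune-to-swale position surrogate), and
`env_effect_fraction` (default 5%) of transcripts respond with a log2
slope of `env_effect_size` (default 1).  Mode counts are exact:
round(fraction × n) per non-conserved mode, remainder to conserved;
per-transcript noise comes from sub-streams keyed by (seed, index).

What it does not emulate: read-level error, positional/GC bias, isoform
structure, gene–gene correlation beyond the shared latent factors,
tagwise dispersion, and library-size/composition coupling (counts are
independent NB, not multinomial — adequate for testing compositional
normalization, by design).  Passing tests therefore certify the
statistical machinery on its own assumptions, not robustness to every
artifact of real libraries.

The companion soil generator draws multivariate-normal site rows with
group-specific means; `soil_for_samples` adds a per-variable gradient
slope (strongest on Na, OM, CEC; near zero on PA) so that soil PC1
recovers the gradient the counts used, letting the pipeline run
end-to-end from files.  The GO generator grows a single-rooted DAG
(each new term gets 1–2 shallower parents within `max_depth`),
annotates gene–term pairs independently with `annotation_density`, and
returns uniform gene scores, pushed toward zero as u^(1+strength) for
genes under enriched terms.

## Numerical choices and degenerate inputs

- All-zero sample columns, zero-variance soil columns, rank-deficient
  OLS designs, non-PSD soil covariances, cyclic or multi-rooted DAGs,
  and terms without annotations raise errors naming the offender.
- Exact-test ties are matched with a 1e-10 log-space tolerance; the
  conditional pmf is normalized before summing.
- λ_GIF is undefined when median(z²) = 0 (error, not NaN).
- Redundancy and elim orderings break ties deterministically (depth
  then id; p then IC then id), so outputs are byte-reproducible.
- Problem sizes in the test suite (≤ 2000 transcripts, ≤ 8 replicates
  per group, 8×30 optimizer instances) are chosen so the full suite
  exercises every stage at statistically meaningful scale while staying
  fast on a single CPU.

## Known limitations

Common (not tagwise) dispersion; a single univariate predictor in the
LFMM (PC1 only, as in the motivating design); GIF-only calibration by
default; no spatial autocorrelation model for sites; the elim-KS p for
a term depends on the test order within a depth level only through
eliminations, which are themselves order-stable by the deterministic
sort.
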