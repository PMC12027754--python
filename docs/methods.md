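# Methods

This note records the models, conventions and design choices behind
`cavpipe`, in the order the pipeline runs them.

## Synthetic cohort model

The generator exists so that every downstream operation can be tested
against known ground truth.  It emulates a post-mortem multi-tissue
cohort at desk scale.

**Causal graph.**  A five-level *terminal-phase context* (death on a
ventilator, plus four Hardy-scale-like points from sudden violent death
to slow death) is the root.  Each category carries an ordinal severity
score in {+1, +0.5, 0, −0.5, −1}.  Severity shifts

- the logit-scale Dirichlet concentration of the CAV1-positive cell types
  (`tp_to_proportions`, default 0.9 per severity unit),
- RIN (`tp_to_rin`, 0.2 RIN units) and ischemic time (`tp_to_ischemic`,
  −120 min),
- and CAV1 itself (`tp_to_cav1`, 0.5 log2 units, a *direct* edge).

Composition feeds CAV1 twice: through the mixture itself and through an
extra `proportions_to_cav1` (default 1.0) log2 units per log2 of the
CAV1-positive cell share.  RIN is additionally coupled to the realized
log2 positive share (`rin_composition`, 0.4 RIN units) on top of its own
Gaussian noise (sd 0.45), making RIN a noisy *proxy* for composition
while the direct RIN → CAV1 path is structurally absent.  This is the
confound the model ladder is designed to expose.

The direct terminal-phase → CAV1 edge deserves a comment: without it,
conditioning on (estimated) proportions would eventually remove *all*
death-related signal, since composition would be the only path.  Observed
cross-tissue cohorts behave otherwise — death circumstances remain
predictive after composition adjustment — so the generator includes a
moderate direct effect.  Effect sizes are not taken from any measured
dataset; they were chosen once so that the recovery analyses are well
powered at the default cohort sizes, and are documented here rather than
presented as empirical estimates.

**Expression model.**  Each cell type has a rate vector: log-normal
(σ = 0.5) baseline per gene, markers multiplied by `marker_fold` (8) in
their own type, CAV1 at rate 20 in positive types and 0.01 elsewhere
(about 0.1–1% of the transcriptome — keeping CAV1 from distorting the
TPM denominator).  Bulk samples mix rates by Dirichlet proportions
(concentration 10 per cell type), are rescaled so columns sum to 10⁶
(exact at zero noise), and then receive multiplicative log-normal noise
(sd 0.2, natural log).  Single-nucleus counts are Poisson around the
type's rate vector scaled to a 2,000-count library.

**What the generator does not model:** realistic transcriptome-wide count
distributions, batch effects, donor-level random effects, doublets,
ambient RNA, sequencing-depth variation beyond library rescale.  Passing
recovery tests therefore demonstrates the *logic* of the pipeline under
its stated assumptions, not robustness to every pathology of real data.

**Determinism.**  Every stochastic step draws from a named substream of
one global seed (`substream(seed, name)` builds a generator from the pair
(seed, crc32(name))), so reruns are bitwise identical and stages can be
toggled without perturbing each other's streams.

## Marker discovery

One-vs-rest two-sided rank-sum test per gene and cell type, on cells
pooled across donors within a tissue.  Conventions:

- exact null distribution when both groups have ≤ 20 cells, mid-rank
  normal approximation with continuity correction above that;
- a gene pooled-constant across cells gets p = 1 (no evidence, and the
  tie-corrected variance degenerates);
- genes are tested only if detected in ≥ 10% of in-type cells — a
  standard guard against never-expressed genes;
- Bonferroni m = genes tested *within one cell-type comparison*, not
  genes × cell types;
- only positive markers (higher in-type mean) are retained in catalogs; a
  negative-direction pass is kept solely to annotate genes (e.g. CAV1) as
  depleted in a cell type.

Consensus: a cell type counts as detected in every tissue whose per-tissue
catalog lists it; a gene is a consensus marker when flagged in at least
⌈n/2⌉ of those tissues (so 2-of-4 and 2-of-3 qualify, 1-of-3 does not).

## Proportion proxies

Scores are *relative* abundances in log units, never normalized to a
simplex — they are regression predictors, not compositions.  The
procedure per cell type: per-sample trimmed mean of all candidate markers
on log2(TPM+1); keep markers with Pearson r > 0.33 against that reference
(strict inequality, Pearson rather than Spearman); recompute the trimmed
mean over survivors as the final score.  Single filter pass, then
recompute — chosen for determinism over iterative refiltering.  The trim
fraction (default 0.05) is removed from *each* tail, and `floor(f·n)`
values are dropped, so small marker sets fall back to the plain mean.
Cell types with fewer than 3 informative markers are excluded with a
recorded reason.

## Model ladder

Per tissue with ≥ 25 samples, y = log2(TPM) of the target gene.

- **Set 1:** OLS on RIN, autolysis score, ischemic time, age decade
  (ordered categorical entered as numeric rank by default), sex, and
  terminal-phase context (one-hot, first level dropped).  Classical
  two-sided t-tests per coefficient; a categorical variable is
  "significant" if the partial F-test over its dummy columns has
  p < 0.05 (one verdict per variable, not per level).
- **Set 2:** the same covariates plus the proportion scores, all
  penalized together in an elastic net on standardized predictors and a
  centered response.  The objective follows the conventional scaled form
  `(1/2n)‖y−Xβ‖² + λ[(1−α)‖β‖²/2 + α‖β‖₁]`; grids are α ∈ {0.4, 0.5, 0.6}
  and λ ∈ {0.05, 0.1, 0.15, 0.2} (elastic-net behaviour enforced, penalty
  always positive), chosen by minimum mean MSE over 10-fold CV repeated 5
  times (no 1-SE rule).  Predictors with nonzero coefficients are refit
  by OLS on their original scales for interpretable β; a factor keeps
  only its selected dummy columns in the partial F-test, and a variable
  selected nowhere counts as not significant in that tissue.  An empty
  selection yields an intercept-only fit, flagged in provenance.
- **Set 3:** every covariate column.  Columns with > 5% missing are
  dropped and listed; the rest are completed by chained equations — up to
  10 sweeps visiting columns by increasing missingness, linear regression
  with predictive mean matching (5 donors) for numeric columns, a
  classification tree for categorical ones — deterministic under one
  seed, a single imputed dataset.  Then selection and refit as in set 2.

The cross-tissue summary counts, per variable and model set, the tissues
with p < 0.05; death-related variables (terminal phase, death manner and
place, cohort, ventilator flag) are also aggregated into one group,
counted when any member is significant.  Variables absent from a set are
reported as absent (NaN), not zero.

## Correlation vectors and MDS

Gene filter: keep genes reaching 4 TPM in strictly more than 5% of the
tissue's samples (a gene at exactly 5% is dropped).  Tissues below 25
samples are excluded throughout.

TMM is applied to TPM columns as the normalization step prescribes —
unusual for TPM, but the pipeline treats filtered column sums as library
sizes.  The implementation follows the published algorithm: reference =
sample whose 75th percentile of depth-normalized values is closest to the
mean of those percentiles; per sample, log-ratios M and abundances A over
genes positive in both; rank-trim 30% of M and 5% of A from each tail;
factor = 2 to the inverse-asymptotic-variance-weighted mean of surviving
M; factors rescaled to geometric mean 1.  It reproduces edgeR's
`calcNormFactors(method="TMM")` to ~1e-7 on integer-count fixtures (an
independent-oracle test runs edgeR via Rscript).

Log transform: log2(TPM/factor + 1) — pseudocount 1.

The TSCV is the standard Pearson correlation of every gene with the
target on log2 values; the target's own entry is set to exactly 1.  Genes
absent after filtering are *missing*, and missingness is preserved in the
assembled tissues × genes matrix: absence of expression is not evidence
of zero correlation.  The only place missing values become zeros is the
explicitly named `zero_filled_export`, provided for algorithms that need
a complete matrix.

MDS is classical (Torgerson): distance(t₁,t₂) = 1 − Pearson over
pairwise-complete genes (default minimum overlap 500 genes, configurable;
an error names any pair below it), double-centering of squared distances,
top-2 eigenvectors scaled by √eigenvalue.  Metric scaling was chosen over
stress-minimizing variants for determinism and its exactness on
Euclidean-realizable inputs (embedding distances reproduce the input
exactly in that case).

## Enrichment

Genes rank by correlation, descending, ties broken by gene id (stable,
input-order invariant).  The enrichment score is the weighted
Kolmogorov–Smirnov running sum with weight exponent p = 1: hits add
|r|ᵖ/Σ|r|ᵖ, misses subtract 1/(N−k); ES is the extremum (positive wins an
exact-magnitude tie).  The permutation null draws random same-size gene
sets — the standard pre-ranked null — and p-values are one-sided within
the observed sign class, `(1 + #{same-sign |ES₀| ≥ |ES|}) / (1 + n_same)`;
NES divides ES by the mean same-sign |ES₀|.  BH adjustment runs within a
tissue across testable sets; sets with no overlap (or outside the 5–2000
size window after intersection) are flagged untestable and excluded from
the BH universe.

The meta-enrichment ranks target *datasets* by first-level NES (NES
rather than a p-derived score, to preserve direction) and treats each
regulator's datasets as a set in a second pre-ranked scan; the resulting
ES is the regulator's GSRS, with dataset-label permutation p and BH
across regulators.  When every regulator owns exactly one dataset the
GSRS ordering reduces to the NES ordering, which is tested.

Cell-type enrichment additionally annotates the target's own marker
status per cell type (consensus-positive / tissue-negative / neither), so
a cell type whose markers co-vary with the target can be distinguished
from one that expresses it.

## Numerical conventions and degenerate inputs

- Readers reject malformed files with line/row locators; empty string and
  "NA" both mean missing; missing numerics stay NaN, never 0.
- OLS refuses rank-deficient designs, naming the collinear columns after
  zero-variance cleanup.
- Permutation p-values never return 0 (the +1 smoothing above).
- All tolerances asserted in tests: Pearson vs sum formula 1e-12, ES vs
  exhaustive enumeration 1e-12, elastic net vs closed form 1e-6, TMM
  invariants 1e-9, MDS closed forms 1e-8.

## Problem sizes

Default test and acceptance runs use 20 tissues × 150 samples for the
confound-transfer analysis, 200 samples for proportion recovery, 200
cells per type for marker recovery, 10⁵ permutations for the enumeration
cross-check, and a 5-tissue × 40-sample cohort for the end-to-end
determinism run — sizes at which every recovery property is comfortably
powered while the whole suite stays desk-scale.

## Known limitations

- Proportion scores are log-scale proxies; they recover rankings, not
  absolute fractions, and share a common component through the TPM
  denominator.
- The chained-equations imputer uses simple per-column learners; it is
  adequate for the covariate tables at hand, not a general MICE suite.
- The permutation GSEA has no multilevel small-p refinement; p-values
  floor at 1/(n_perm+1).
- Scale equivariance of proportion scores holds exactly only above the
  +1 pseudocount regime (high-TPM markers); rankings are stable in
  practice.
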