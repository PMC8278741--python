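# Methods

This note documents the models and procedures implemented in `hgfmet`, the
assumptions behind them, the design choices that were genuinely open, and
what the synthetic cohorts do and do not establish about real data.

## Activation labelling

**Model.** In samples where HGF/c-MET signalling is active, ligand and
receptor are co-expressed; in inactive samples their expression is
decoupled. Each gene is min–max scaled to [0, 1] over tumor samples and a
sample is called activated when scaled-HGF / scaled-MET ∈ [0.5, 1.5].

**Choices.**
- *Ratio orientation* is HGF/MET (ligand over receptor). The window is
  nearly symmetric under inversion, so orientation has limited effect.
- *Both window endpoints are inclusive*: a ratio of exactly 0.5 or 1.5 is
  activated. This is auditable in `classify_activation` and its tests.
- *Scaled MET = 0* leaves the ratio undefined; the sample is labelled
  inactivated (an unexpressed receptor cannot support ligand signalling)
  and flagged with a NaN ratio.
- *Scaling scope*: the pooled tumor cohort by default;
  `per_cancer_scaling=True` rescales within each cancer type instead.
- Normal-tissue samples receive no activation label; the differential
  contrast downstream is activated vs inactivated *tumors*.

The Pearson correlation reported for the called activated group is
computed on raw expression and is typically higher than the planted
latent correlation, because samples called activated are precisely those
with proportional ligand/receptor values (a selection effect any
window-based rule shares).

## Immune-gene differential screen

Welch's unequal-variance t statistic with Welch–Satterthwaite degrees of
freedom, two-sided, on log2(x + 1) expression. Genes with raw p < α
(default 0.05) form the differential table; log2 fold change uses a
pseudo-count of 1 and is descriptive only. No multiplicity correction is
applied by default, mirroring the screening role of this stage;
Benjamini–Hochberg is available via `adjust="bh"`. When both group
variances are zero the test is undefined and we set p = 1 if the means
agree, p = 0 otherwise. An ordinary t statistic was preferred over a
moderated (empirical-Bayes) one: at the group sizes this pipeline targets
(≥ ~50 per group) variance moderation changes little, and the plain
statistic has an exact independent oracle for testing.

## Over-representation analysis

Hypergeometric upper tail P(X ≥ k) for overlap k between the screened
genes (query) and each set, inside a fixed universe. The universe is the
immune-gene list intersected with the matrix — matching the query pool is
what keeps the test calibrated. Set sizes are taken after intersection
with the universe. Sets overlapping the query by fewer than
`min_overlap = 2` genes are not reported (singleton overlaps carry no
information for downstream scoring), but BH q-values are computed over
*all* tested sets so the filter does not bias the adjustment. Ordering is
deterministic: p ascending, then set size descending, then name. Because
the hypergeometric is discrete, the attainable level at nominal 0.05 is
slightly conservative; the calibration test compares the empirical
false-positive fraction against the exact attainable level rather than
against 0.05 itself.

## Pathway imbalance score and degree score

For pathway P with up-members i = 1..m and down-members j = 1..n:

    A(P) = log2( sqrt(Σ_i ω_i (X_i − μ_i)²) / sqrt(Σ_j ω_j (X_j − μ_j)²) )
    DS(P) = (A(P) − μ′) / sd′

- **Expression scale**: X is log2(x + 1), the same scale as the screen.
- **Reference means μ**: per-gene means over the inactivated tumor group
  by default (the pathway-quiet state); `reference="normal"` switches to
  normal-tissue samples. This was an open design point — the reference
  population is not intrinsic to the score — so it is a config switch.
- **Weights ω** (computation not intrinsic to the score either): the mean
  absolute Pearson correlation of each member gene with its co-members,
  normalized to mean 1 over the pathway and floored at 1e-6. A constant
  gene contributes zero correlations and receives the floor with a
  warning. A is invariant to rescaling all weights by a positive constant.
- **Permutation null**: each of `n_perm = 1000` draws samples m + n genes
  without replacement from the immune pool; the first m of the uniformly
  shuffled draw act as the up-set (any fixed rule is valid by
  exchangeability). Weights and reference means are recomputed per draw so
  the null mimics the full scoring procedure. μ′ and sd′ are the
  *per-sample* mean and SD over draws (whether to pool across samples was
  open; per-sample standardization is what makes DS comparable across
  samples with different baseline dispersion). The implementation
  precomputes the pool's correlation matrix and squared deviations once
  and evaluates draws by indexed tensor products; this is algebraically
  identical to per-draw recomputation (verified against a naive per-draw
  oracle in the tests) and makes 1000 draws on a 250-sample cohort take
  well under a second.
- **Degenerate cases**: a zero denominator (or numerator) flags the
  sample's A as undefined (NaN) rather than ±∞; sd′ = 0 flags DS as
  undefined. Undefined values propagate as NaN and never silently become
  zeros.
- **Group contrast**: two-sided Welch test of DS between activation
  groups, with the direction of the activated-group mean.

Note a structural property of the score: because deviations enter
squared, A is blind to the *sign* of a gene's shift; a pathway whose up-
and down-members deviate by equal magnitudes in a sample shows A ≈ 0
regardless of direction. A pathway separates the groups only when the
deviation magnitudes of its up- and down-sets differ. The synthetic
generator therefore plants up-shifts larger than down-shifts (below).

## Immune deconvolution

Per sample, non-negative least squares ‖b − S·f‖² with f ≥ 0 on
linear-scale expression (mixing is additive on the linear scale), followed
by simplex normalization. The unnormalized coefficient sum is kept as an
*abundance* — an absolute-infiltration proxy that, unlike the simplex
fractions, responds to how much total immune content a sample carries;
the activated-vs-inactivated infiltration contrast is tested on it.
Markers missing from a sample are dropped from both b and S (zero
imputation would bias fractions toward cell types with absent markers);
an overlap below 50% is an error. An all-zero NNLS solution yields
uniform fractions with a degeneracy flag. Correlations of fractions with
HGF/MET are Pearson; when tumor purity is supplied, a first-order partial
correlation (residualizing both variables on purity) is added, since
fractions and purity are mechanically entangled in bulk tissue. Exactly
collinear inputs leave the partial correlation undefined (NaN), not zero.

## Diagnostic classifier

Features: the cell-type fractions, the degree scores of the top-k
pathways ranked by the group-contrast p-value (all pathways, with a
warning, if fewer than k = 20 are scoreable), and log2 HGF and MET. The
classifier is a single-hidden-layer feed-forward network — 16 logistic
units, logistic output, weighted cross-entropy, full-batch gradient
descent (2000 epochs, learning rate 0.3, momentum 0.9, L2 1e-4),
seed-controlled initialization — the smallest architecture that is
genuinely a neural network yet trains in seconds and is exactly
reproducible. It is implemented in numpy rather than via a library
estimator so that inverse-class-frequency sample weights enter the loss
directly (normal tissue is the minority class in the cohorts this
targets). Evaluation is stratified 5-fold cross-validation;
standardization parameters and class weights are computed on training
folds only (a leakage test asserts that a globally-standardized variant
diverges), and out-of-fold probabilities are pooled into a single ROC.
AUC is computed by trapezoid over the threshold sweep and equals the
normalized Mann–Whitney U; accuracy is reported at the fixed 0.5
threshold.

## Survival

Features are dichotomized at the median (ties at the median go to the low
group — deterministic and conservative). The two-group log-rank statistic
accumulates observed-minus-expected events in one group and the
hypergeometric variance at each distinct event time (tied event times
handled with the (n_t − d_t)/(n_t − 1) correction; risk sets of size 1
contribute nothing), referred to chi-square with 1 df. The implementation
is cross-checked against `lifelines.statistics.logrank_test` in the test
suite; Kaplan–Meier coordinates for plotting come from lifelines.
Overall survival is the assumed endpoint.

## Synthetic cohorts: what is planted, and what passing tests show

`SyntheticConfig` defaults define the study conditions: 100 activated +
100 inactivated tumors, 50 normals; 200 immune genes (40 planted up at
+2 log2, 20 planted down at −1 log2), 300 background genes; 6 cell types
× 10 markers; latent HGF–MET correlation 0.8 in activated samples;
log-normal noise with sdlog 0.5; a 2× infiltration coefficient in
activated tumors; hazard ratio 2 between risk groups with 30% censoring.

- **Anchor genes.** Activated samples form a compact co-expressed cluster
  (ln-scale SD 0.35, centered 1.5 ln-units above the gene baseline) whose
  shared latent factor hits the target correlation analytically.
  Inactivated samples draw independent ln-offsets, mostly uniform over
  ±6 (≈ e¹²-fold dynamic range, so an uncorrelated pair rarely lands in
  the ratio window) with a ~10% subpopulation pinned near the extremes —
  a saturated/silenced bimodality that also stabilizes the per-gene min
  and max on which the scaling depends.
- **Differential genes.** Up-shifts are planted larger than down-shifts
  (`down_effect_scale = 0.5`). This mirrors the up-dominant differential
  signal the pipeline is designed around and is what makes planted
  pathways detectable by a sign-blind quadratic imbalance score (see the
  structural note above): with exactly symmetric magnitudes, a mixed
  pathway's A(P) is identical in both groups by construction.
- **Mixtures.** Marker-gene expression is exactly
  (infiltration coefficient) × S·f plus multiplicative log-normal noise,
  so at zero noise deconvolution must recover fractions exactly. Tumor
  and normal mixing fractions use a decreasing Dirichlet profile and its
  reverse, giving the two compartments distinct mean immune compositions.
- **Survival.** Exponential event times (baseline rate 0.1 per time
  unit), hazard multiplied in the high-risk (activated) group;
  independent exponential censoring calibrated to the target censored
  fraction.

The generator does *not* emulate per-cancer TCGA distributions, batch
effects, gene–gene correlation beyond the planted blocks, count noise, or
marker genes shared between cell types. Passing tests therefore show that
each estimator recovers the structure it assumes, at realistic effect
sizes and noise — not that real cohorts satisfy those assumptions. In
particular the headline numbers of the worked example (93% label
agreement, AUC ≈ 0.95) characterize the generator's geometry, not any
real cancer cohort.

## Problem sizes used in the test suite

The statistical tests run at the sizes their claims name: 10,000
replicates for Welch type-I error, 1000 cohorts of n = 200 for log-rank
calibration, 10,000 random queries for enrichment calibration, 1000
permutation draws wherever a degree score is asserted, 50 seeds for label
agreement, differential recovery and pathway ranking, 20 seeds for
deconvolution error, and 10 full pipeline runs for the end-to-end AUC.
Pathway-ranking simulations use 200 permutation draws per pathway: the
group contrast compares DS *between* samples, and the draw count affects
only the per-sample standardization, not the ranking resolution.

## Known limitations

- The ratio window treats scaled expression as comparable across genes;
  with extreme outliers min–max scaling compresses everything else.
- The co-expression weights are a design choice; other network weights
  (e.g., topological overlap) would change A(P) quantitatively.
- NNLS deconvolution has no per-sample significance test and assumes the
  signature spans the immune content; unmodelled cell types leak into the
  residual and the abundance proxy.
- The classifier is intentionally small; it is a faithful evaluation
  harness, not a tuned predictor.
- Cox regression and multivariable survival modelling are out of scope;
  only two-group log-rank comparisons are provided.
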