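# Methods

`brewlink` quantifies how much of a metabolite panel measured in naturally
aged huangjiu (Chinese rice wine stored for years in sealed pottery jars)
is predictable from the jar's physiochemical state and from the bacterial
community of its lees — and which features carry that predictability. The
package implements the full chain: quality control and transformation of
the three measurement layers, assembly of named predictor groups,
per-metabolite cross-validated prediction, bootstrap inference on the
explained variance, and Shapley-value attribution. Because no cohort of
this kind is publicly deposited, the package ships a synthetic-data
generator with planted, machine-readable ground truth; every stage is
validated against that truth.

## The modeling problem

For each metabolite *m* with standardized level *y* and a feature matrix
*X* (samples × features), the pipeline estimates how well *y* can be
predicted out-of-sample. Five-fold cross-validation produces one pooled
out-of-fold prediction vector ŷ per repeated run, scored by

- explained variance, EV = 1 − Var(y − ŷ)/Var(y), and
- coefficient of determination, R² = 1 − Σ(y − ŷ)²/Σ(y − ȳ)².

Both use the pooled ŷ, not per-fold averages; variances use the sample
(n−1) denominator (the ratio is denominator-invariant). EV ignores a
constant prediction offset; R² does not and can be negative out-of-fold.

Learners: lasso regression as the linear baseline; random forest, LightGBM
and XGBoost as tree ensembles. Inside each training fold an optional
random hyperparameter search (10 draws, inner 3-fold CV, default spaces
documented in `learners.py`) selects a configuration before refitting on
the whole training fold. The random forest instead uses a fixed
configuration by default — 100 trees, depth 5, ≥5 samples per leaf, ≥2 to
split, 10 features per split (capped at the matrix width for narrow groups
such as the 6-column physiochemical set) — and regression trees split on
squared error; a "Gini" criterion exists only for classification, so a
Gini setting requested for a regression forest resolves to squared error.

## Preprocessing

Metabolites: compounds with fewer than 50 non-missing measurements are
dropped; remaining missing values are imputed with the per-metabolite
minimum of the observed values (reading missingness as censoring at the
detection limit); values are log10-transformed and z-scored (sample sd).
An optional switch residualizes each metabolite on storage time by OLS and
re-standardizes; it is off by default because aging year is itself a
predictor of interest and removing it up front would bleed signal out of
every year-containing feature group. A metabolite that becomes constant
after residualization is returned as zeros and flagged rather than raised.

Taxa: relative abundances at species and genus level are filtered to taxa
with strictly more than 0.1% mean relative abundance present in strictly
more than 10 samples, then transformed per sample with the centered
log-ratio (CLR), clr_i = ln x_i − mean_j ln x_j over the retained taxa,
after flooring zeros at 1e-10. Rows are not renormalized after filtering:
CLR is invariant to row rescaling, so renormalization would change
nothing. Note the zero replacement breaks exact scale invariance for
samples containing zeros (the floor does not scale with the row); the
invariance property holds exactly on strictly positive rows and that is
how it is tested.

Alpha diversity (Chao1, Shannon, Simpson) is computed per sample from the
count tables via scikit-bio, on the *unfiltered* counts (richness
estimators need the rare taxa). Defaults follow the QIIME 2 conventions:
Shannon in bits (base 2, switchable), Chao1 in the bias-corrected
small-sample form S_obs + F1(F1−1)/(2(F2+1)) (classical form switchable),
Simpson as 1 − Σ p_i².

## Feature groups

Six ablation groups: PI (five physiochemical indexes + aging year), AMS /
AMG (species- / genus-level CLR abundances + the three diversity indices
at that level), AFS / AFG (the same plus aging year), and FM (the union,
aging year once, diversity indices kept at both levels under distinct
names). Columns are ordered block-wise then alphabetically; constant
columns are dropped with a warning. The groups satisfy AMS ⊂ AFS ⊂ FM and
PI ⊂ FM by construction, which the tests assert.

## Bootstrap significance

Each of B iterations (default 100) draws a fresh 5-fold partition,
resamples every training fold with replacement to its original size
(held-out folds are never resampled), trains the fixed-configuration
learner, and scores the pooled out-of-fold predictions. The 2.5/97.5
percentiles of the B values give the 95% CI; the p-value against the
"no variance explained" null is the add-one empirical tail
p = (1 + #{EV_b ≤ 0})/(B + 1), so p ∈ [1/(B+1), 1], and a metabolite is
"significantly explained" when p < α (default 0.05). This one-sided
empirical definition is the package's own; no multiple-testing correction
is applied by default, but a Benjamini–Hochberg helper is provided.
Hyperparameter search does not run inside the bootstrap: iterations reuse
the learner's fixed (or previously selected) configuration, keeping the
bootstrap an inference on the fitting procedure actually used rather than
a 30-fold more expensive search-plus-fit compound.

## Shapley attribution

Tree-ensemble predictions are decomposed with the path-dependent Tree SHAP
algorithm, implemented in-package for sklearn decision trees and random
forests: the cooperative game's value function is the tree-traversal
conditional expectation (features outside the coalition are integrated out
by descending both children weighted by training cover), and the
polynomial-time path algorithm computes exact Shapley values for it.
Local accuracy (base value + Σ contributions = prediction) is enforced in
tests at 1e-6, and the implementation is validated against brute-force
enumeration of all feature coalitions on small trees. LightGBM and XGBoost
models are attributed through their built-in `pred_contrib` outputs, which
implement the same algorithm. Linear models are not attributed.

Attribution runs on held-out folds (each fold model explains the samples
it never saw), pools |SHAP| over the folds of a run, averages over runs,
and signs each feature's mean |SHAP| by the Spearman correlation between
the raw feature and the metabolite over all samples ("directional mean
absolute SHAP"). Zero or undefined correlation gives sign 0. Because both
metabolites and CLR features are standardized, these values are comparable
across metabolites; the comparability is statistical, not bitwise — a unit
change of raw concentrations leaves z-scores identical up to ~1e-15, which
can still flip individual tree splits, so the tests assert identical signs
and magnitudes within a small tolerance. A train-set attribution switch
exists for diagnostics. Whether to average before or after pooling folds
is a genuinely open choice; pooling held-out samples first, then averaging
runs, was chosen because it weights every sample equally.

## Descriptive layer

Spearman correlation matrices (average-rank ties, t-approximation
p-values, pairwise-complete missing handling, NaN below 3 complete pairs)
screen index–metabolite associations. Metabolites whose explained variance
exceeds 0.3 are clustered two-way (metabolites and samples) by
hierarchical clustering — Euclidean distance, average linkage, both
configurable, cut to 3 clusters per axis by default — and a one-way ANOVA
tests each physiochemical index across the sample clusters. Cluster labels
are renumbered by first appearance over sorted metabolite names so they do
not depend on input column order. Dendrograms export as Newick.

## Synthetic data generator

The generator emulates the statistical shape of an aging-huangjiu cohort:

- 110 samples at aging years {3, 8, 10, 20, 25} (uniform weights by
  default, configurable).
- Physiochemical indexes on realistic scales (total acid ~5 g/L rising
  with age; pH ~4 falling with total acid; amino nitrogen, reducing sugar,
  conductivity with mild age/acid trends). Only the rank structure matters
  downstream, so magnitudes are design choices.
- A species table (60 species in 25 genera by default) drawn log-normally
  around a geometric rank-abundance curve and renormalized to the simplex,
  with one dominant species calibrated so its mean relative abundance
  matches the configured 0.59 (a ×1.13 correction offsets the Jensen bias
  of renormalization at the default noise scales); one species rises with
  aging year, one with total acid, one falls with age. Sub-detection
  abundances (<1e-4) are zeroed and rows renormalized, creating the zeros
  that exercise CLR zero replacement. Counts are multinomial draws at
  10,000 reads/sample, so count-based diversity indices behave like real
  sequencing summaries.
- Metabolites are built from a planted effect table: each effect
  contributes coefficient × g(standardized source), where the source is
  aging year, a species' CLR abundance, or an index, and g is linear,
  saturating x/(1+|x|), a threshold indicator above the median, or a
  product with a second source. The sum plus N(0, noise_sd²) noise
  (default sd 0.5) is standardized and exponentiated to a positive
  concentration. Metabolites without effects are exponentiated pure noise.
- Missingness is injected by censoring the lowest censor_quantile fraction
  (default 5%) of each metabolite, ties broken by sample position. The
  real missingness mechanism of such panels is unknown;
  censoring-below-quantile is an assumption and is flagged as such.

A single seed fans out to fixed-offset child streams per stage, so a
dataset is bit-reproducible and stages are independently stable. The
ground truth records every planted effect with its sign for recovery
testing.

What the generator does *not* emulate: sequencing reads, chimeras or ASV
inference; chromatography-level measurement error; correlated metabolite
blocks beyond shared drivers; batch effects. Passing recovery tests on
this generator therefore demonstrates that the pipeline's machinery is
correct under its stated assumptions, not that any particular real cohort
satisfies them.

## Numerical and design choices

- Sample (n−1) standard deviations everywhere a z-score is taken.
- Strict inequalities in the taxa filters, as the thresholds are printed.
- Fold partitions are seeded per (metabolite, run) by hashing the
  metabolite name into a seed stream, so adding a metabolite never
  perturbs another's folds.
- Lasso's search space for the regularization strength is log-uniform on
  [1e-3, 10]: below 1e-3 the penalty is inactive at n ≈ 110 and
  coordinate descent converges very slowly for no accuracy gain.
- The learner-comparison criterion counts metabolites with R² > 0.3 and,
  separately, EV > 0.3 (the two thresholds answer slightly different
  questions; both are reported).
- Degenerate inputs raise early with the offending entity named: constant
  metabolites, all-zero count rows, nonpositive concentrations before the
  log, sample-ID mismatches (reported as the symmetric difference).

## Problem sizes used in validation

The acceptance checks run the generator at the cohort's design size
(110 samples) but keep Monte-Carlo depth modest by design: bootstrap
type-I control uses 200 null metabolites at B = 50 with the linear
learner; ablation medians use 10 generator seeds; the learner benchmark
uses 10 repeated runs of a 10-metabolite suite. These sizes give stable
medians/fractions for the qualitative claims being checked while keeping
the whole validation run on a single CPU in minutes.

## Known limitations

- BIOM input is not supported; taxa tables are TSV.
- Attribution is defined for tree ensembles only (no linear-model SHAP,
  no interaction values).
- The bootstrap p-value is an empirical add-one tail, bounded below by
  1/(B+1); at B = 100 the smallest reportable p is ~0.0099.
- No rarefaction, beta diversity, or phylogenetic diversity.
- The cluster map's 3/3 cluster counts are display conventions, not
  inferred numbers of clusters.
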