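# Methods

This note records the models implemented in `omicsfuse`, the parameter
choices that matter, what the synthetic cohorts do and do not emulate,
and the numerical decisions taken where the design was genuinely open.

## Similarity network fusion

Each molecular layer is mean-imputed per feature, z-scored, and turned
into a patient similarity network with a locally adaptive Gaussian
kernel on Euclidean distances:

    W(i,j) = exp( − d²(i,j) / (α · ε(i,j)) ),
    ε(i,j) = (μᵢ + μⱼ + d(i,j)) / 3,

where μᵢ is the mean distance from sample *i* to its K nearest
neighbours.  Zero-variance features are dropped with a warning; a layer
of all-identical samples is rejected (zero bandwidth).  Two matrices are
derived per layer: the *status* matrix P (off-diagonal `W/(2·rowsum)`,
diagonal ½) and the *local* kernel S (row-normalized over each sample's
K most similar neighbours, self excluded).  Fusion cross-diffuses the
status matrices through the other layers' local kernels,

    P_v ← S_v · mean_{w≠v}(P_w) · S_vᵀ ,

updating all layers simultaneously from the previous iterate, then
symmetrizing and row-renormalizing each P_v; the fused network is the
symmetrized mean of the final status matrices.  Defaults K = 24,
α = 0.7, t = 25 iterations suit cohorts of a few dozen samples; α in
[0.3, 0.8] is the recommended band, and K must stay below n.

**Spectral clustering and the self-loop choice.**  Clustering uses
k-means (100 restarts, fixed seed) on the row-normalized bottom-k
eigenvectors of the normalized Laplacian.  The Laplacian is built from W
with its diagonal zeroed.  The kernel above decays like
exp(−d̄/α) in the typical inter-sample distance d̄, so for a couple of
hundred standardized features the off-diagonal entries are ~10⁻¹²
against self-similarities of 1; keeping the self-loops collapses the
Laplacian into numerical noise (the spectral embedding of a clean,
well-separated layer then degenerates, which we observed directly).
Dropping self-loops is the standard graph-clustering treatment, changes
nothing for exact block-structured affinities, and makes the embedding
invariant to the kernel's overall decay scale.  The eigengap estimator
returns the k in {2..k_max} with the largest gap between consecutive
Laplacian eigenvalues, ties toward smaller k; a best gap below a
configurable floor (default 0.05) is flagged as weak, since a
structureless (complete-graph-like) network produces a flat spectrum.

## Diagonal regularized NCA

Feature weights for one layer are learned by maximizing

    F(w) = (1/n) Σᵢ Σ_{j≠i, yⱼ=yᵢ} p_ij − λ Σ_r w_r²,
    p_ij = exp(−d_w(i,j)) / Σ_{k≠i} exp(−d_w(i,k)),
    d_w(i,j) = Σ_r w_r² · |x_ir − x_jr|,

i.e. a soft leave-one-out nearest-neighbour accuracy with a weighted-L1
distance; the optimization variable w is unconstrained and the reported
per-feature weights are w_r² ≥ 0.  Default λ = 1/n.  Optimization is
full-batch gradient ascent (at most 200 epochs, initial step 1.0) with
halving backtracking, so the objective trace is non-decreasing and the
fit is fully deterministic — no random initialization is used.  Weights
start uniform, scaled so the mean pairwise distance is 1: for a
high-dimensional layer an unscaled start saturates the softmax (every
p_ij collapses onto the single nearest neighbour) and gradients become
uninformative.  Panels are selected either as the top-n weights (to pin
a panel size) or by a weight threshold (default 2% of the maximum
weight); the minimal-panel search evaluates sizes 3–10 by stratified
5-fold CV loss of a caller-chosen classifier, ties toward the smaller
size.

## Classifiers

"Cubic KNN" is K-nearest-neighbours under Minkowski distance with
exponent 3 (default 10 neighbours, uniform votes); "quadratic SVM" is a
degree-2 polynomial kernel (coef0 = 1), "coarse Gaussian SVM" an RBF
kernel with a large kernel scale; bagged decision trees complete the
set.  SVM posteriors come from sigmoid (Platt) calibration fitted on
internal training folds; KNN posteriors are neighbour vote fractions.
All preprocessing (standardization, calibration) is fitted inside
training folds only — a label-shuffle control lands within binomial
noise of chance, which is the test for leakage.  Predictions carry a
low-confidence flag when the maximum posterior is strictly below 0.7.
Hyperparameter tuning minimizes 5-fold CV loss by random search
(log-uniform for scale-like parameters, default budget 60); any search
strategy honouring the same contract may be substituted.

Cohort transfer re-expresses both cohorts in their own
standard-normalized coordinates before the model is re-fitted and
applied: the point of the normalization is to absorb platform-level
location/scale shifts, so the training matrix must live in the same
self-normalized space as the external one.  Panel features missing from
the external cohort are dropped from both sides (error below 50%
coverage), and the supervised labels are compared with an unsupervised
hierarchical clustering (cosine distance, complete linkage) of the same
external matrix via best-label-matching agreement.

## Drug-response prediction

Cell-line biomarker profiles are standard-normalized per feature and
stored in an exhaustive searcher; queries return the n = 10 references
with smallest squared Euclidean distance, ties broken by id.  Activity
areas are z-scored per drug across lines (sample sd), and categorized
with strict inequalities: z > 0.8 sensitive, z < −0.8 resistant,
boundaries inclusive-intermediate.  A query's per-drug prediction is the
category of the *median* of its data-bearing neighbours' z-scores —
median over continuous z, then categorize, which coincides with the
mean when exactly two neighbours carry data; neighbours without drug
data are skipped, not replaced.  Agreement is the quadratic weighted
Cohen's kappa, κ = 1 − Σw·O / Σw·E with w_ij = (i−j)²/(C−1)² and E the
product of the marginals, over the full category grid even when some
categories are unobserved; two constant identical vectors score 1 by
convention.  The leave-one-out benchmark predicts every data-bearing
line with itself excluded and reports per-line and mean kappa; a
single-drug table switches to one kappa pooled across lines (per-line
kappa is degenerate there) and logs the switch.

## Statistics

Differential abundance uses Welch's unequal-variance t-test per feature
on normalized continuous values for every layer, with Benjamini–Hochberg
step-up q-values (via `statsmodels`); features with zero variance in
both groups get p = 1 and a degeneracy flag rather than an error.  Tests
are two-sided with the direction reported separately.  Enrichment is the
upper-tail hypergeometric over-representation test on
universe-intersected gene sets (GMT input), BH-corrected across terms.
Survival uses the Kaplan–Meier product-limit estimator per group
(`lifelines`), median = smallest time with S(t) ≤ 0.5 (NaN when not
reached), and the two-sample (or multivariate) log-rank test.
Categorical association uses Pearson chi-square without continuity
correction for r×c tables and Fisher's exact test for 2×2, dropping
zero-margin rows/columns with a warning.

## Synthetic cohorts

`standard_scenario()` is the reference design: 45 samples, two
near-balanced subtypes, four layers (mRNA 200 features / 40 informative,
protein 100/20, miRNA 60/12, methylation 200/40), standardized effect
size 2, unit Gaussian noise, and 40% discordant samples on three of the
four layers.  Informative feature *j* is elevated in subtype
`1 + j mod k`, a pattern fixed by the feature index so that feature
semantics are identical across independently generated cohorts (which is
what makes cross-cohort classifier transfer meaningful).  Column order
is shuffled per seed with ids travelling along, and ground-truth
informative ids are recorded.

**Why 20% informative features.**  Affinity-based clustering of a layer
works through pairwise distances, where the between-subtype excess
(≈ 2·k_inf after standardization) must clear the noise floor of the
squared distance (sd ≈ √(8p)).  At effect size 2 this puts the cliff
near 10% informative: a 200-feature layer with 20 informative features
clusters at chance even without discordance, while 40 informative
features give perfect recovery.  Since the generator's contract is that
*clean layers carry recoverable signal* and only discordance degrades
them, the design point is 20%.

**Discordance.**  In each discordant layer, a window of 40% of the
samples (windows roll through a per-cohort shuffled order, overlapping
as little as the fractions allow) has its informative-feature rows
permuted among themselves — marginal feature distributions are exactly
preserved.  Roughly half of each window swaps signatures pairwise with a
member of the other subtype (these samples now mislead that layer); the
rest rotate within their own subtype.  Crossing is tracked globally so
no sample carries a wrong-subtype signature in more than one layer:
three windows of 40% cannot be disjoint (3 × 0.4 > 1), but the crossing
sets (3 × ~20%) can, and that disjointness is precisely what keeps the
multi-layer consensus recoverable while each discordant layer alone
clusters at ARI ≈ 0.3.

**Drug panels and survival.**  Per drug, subtype means are evenly spaced
over [−e, +e] for subtype effect e, with an orientation alternating
deterministically by drug index, plus Gaussian noise.  This calibration
makes the per-drug z-means of the two subtypes sit at
±e/√(σ² + e²) — beyond the ±0.8 category boundary for the default
(e = 2, σ = 1), so the ordinal categories genuinely reflect subtype and
the neighbour-median predictor is informative (measured mean κ ≈ 0.62);
halving the span would pin every z-mean inside the intermediate band and
no predictor could score well.  Survival times are exponential with a
per-subtype scale (months); censoring is an independent coin flip at the
configured rate, with censored times drawn uniformly below the event
time.

**What the generator does not emulate.**  All layers are unbounded
Gaussian — including "methylation", which in real data lives in [0,1]
(beta values) — and features are independent given the subtype, so
there is no co-expression structure, no batch effects, no missingness
pattern, and no dose-response curve behind the activity areas.  Passing
tests therefore demonstrate the correctness and calibration of the
algorithms under planted structure, not performance on real cohorts.

## Pipeline conventions

The orchestrated run executes simulate → fuse → cluster → biomarkers →
classify → transfer → drugs → stats.  The biomarker/classifier stages
default to the methylation layer: it is the concordance-intact layer of
the reference design, and a panel meant to track the *consensus*
subtype should be mined from a layer that is not itself discordant with
the consensus (a panel from a 40% discordant layer caps truth-accuracy
near 0.8 no matter the classifier).  Every stage writes a provenance
sidecar (config hash, seed, stage version, output checksums); reruns
skip stages whose outputs verify, and identical config + seed gives
byte-identical outputs.

## Known limitations

* The affinity kernel's likelihood-style scale makes raw off-diagonal
  entries astronomically small in high dimension; all downstream
  operations use normalized quantities, but exported raw networks should
  be interpreted relatively, not absolutely.
* NCA is non-convex; the deterministic uniform initialization makes fits
  reproducible but a different basin could exist for adversarial inputs.
* The minimal-panel search inherits the variance of 5-fold CV at n ≈ 45;
  tie-breaking toward smaller panels is a deliberate parsimony bias.
* Quadratic kappa is undefined for a single usable pair in spirit (it
  returns a formula value); benchmark interpretation should rest on the
  mean over lines.
* With more than two subtypes the differential-testing stage is skipped
  (Welch t is two-group); the clustering, panel and drug stages are
  k-agnostic.
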