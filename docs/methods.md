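# Methods

This note documents the statistical models, numerical choices and
deliberate design decisions behind `ifcstate`, and states what the test
suite's green checkmarks do and do not establish.

## The classification problem

A feature table is an m × n real matrix X (rows = cells, columns =
features) with optional class labels y drawn from n_c ≥ 2 classes.  The
workflow learns a mapping f : Rⁿ → {c₁, …, c_{n_c}} from a labeled
reference measurement and applies it to unlabeled populations.  Two
deployment modes matter in practice: per-cell calls (gating
replacement) and population composition (the fraction of apoptotic
cells per timepoint of a kinetics experiment, reported by
`kinetics-report` as #predicted-apoptotic / #cells).

## Feature filters

All three filters operate per fold on the scaled training data and are
cheap enough to refit inside cross-validation.

**Discretization.** Mutual information is estimated on equal-frequency
(quantile) bins, default B = 10.  Bin edges are the j/B quantiles
(linear interpolation); values are placed with a left-open search so
that equal values always share a bin — a constant feature occupies a
single bin, and any strictly increasing transform of a feature yields
identical bin indices.  Quantile binning was chosen over equal-width
because fluorescence intensities are heavy-tailed: a single bright
outlier would otherwise claim most of the range.  B is exposed as a
parameter because no canonical value exists; rankings are insensitive
to B over 5–20 on the synthetic fixtures.

**MIM.** The plug-in estimate I(χᵢ, c) in bits (log base 2 — the base
rescales but never reorders).  Empty joint cells contribute zero
(0·log 0 := 0); the estimate is clipped at 0 against −1e-16-scale
rounding.  The estimator is verified against a brute-force double
summation to 1e-12 bits on 1000 random joint tables.

**mRMR.** Greedy stepwise selection: the first feature is the MIM
winner; each later step adds the candidate maximizing relevance minus
mean mutual information to the already-selected set, with
feature–feature MI computed on both features' own quantile grids.
Features beyond the requested selection depth are appended in MIM
order so that "take the top n_FS" is well defined for every n_FS — this
lets model selection treat n_FS uniformly across all three filters.
Score ties break to the lowest original feature index (deterministic).

**Fisher score.** Ψᵢ = Σₖ mₖ(μᵢₖ − μᵢ)² / Σₖ mₖ σᵢₖ² with *population*
class variances (ddof = 0), matching the plain σ² of the definition;
the convention is stated so external oracles can match it exactly.  A
feature constant within every class has a zero denominator: if the
class means also coincide the score is 0; if they differ the feature is
perfectly discriminative and receives a large sentinel (1e12, ranked
first) with a logged warning.

## Scaling

Features spanning orders of magnitude distort distance-based and
covariance-based classifiers, so tables are standardized (default) or
min-max normalized before filtering and training.  Parameters are
estimated on training data only — sample standard deviation (ddof = 1)
for standardization — and applied unchanged to validation, test and
deployment data.  Constant training features get scale 1 and map to 0.
Values outside the training normalization interval are *not* clipped:
clipping would distort distances for KNN and the SVM kernel.

## Classifiers

**LDA / QDA.**  Gaussian class-conditional models; the predicted class
maximizes log P(x|cₖ) + log P(cₖ), evaluated in log space via Cholesky
factors (stable where naive densities underflow).  Pooled covariance
uses denominator m − n_c; per-class covariances use mₖ − 1.  Equal
priors are the default (appropriate when deployment class frequencies
are unknown and the reason LDA/QDA degrade gracefully under training
imbalance); empirical priors are available by flag.  When a covariance
is ill-conditioned (condition number > 1e8) a ridge of
1e-6 · trace(Σ)/d is added to the diagonal — IFC exports contain
near-duplicate features that make covariances numerically singular.
Posterior argmax ties resolve to the earlier class in class order.

**KNN.**  Euclidean majority vote over the k nearest training rows.
Tie conventions, all deterministic: equal distances at the k-th
neighbor are included by stable training-row order; a tied vote goes to
the class of the nearest neighbor belonging to a tied class (locality-
respecting).

**LLSVM.**  Gaussian-kernel SVM linearized by a Nyström map:

1. *Landmarks*: Lloyd's k-means from k-means++ seeding, run to an
   assignment fixpoint (cap 300 iterations); an emptied cluster is
   re-seeded from the point farthest from its current center.
   Deterministic per seed.  Default p = min(m, 100) landmarks — no
   canonical value exists; p is a search-space dimension.
2. *Map*: with W the landmark kernel matrix and W = UΛUᵀ truncated at
   eigenvalues ≤ 1e-10 · λ_max (the numerical rank of Gaussian kernel
   matrices), z(x) = Λ^{−1/2} Uᵀ k(x, L).  With p = m the map
   reproduces the exact kernel matrix entrywise.
3. *Linear SVM*: the primal ½‖w‖² + C Σ hinge is solved through its
   dual by SMO with second-order (maximal-gain) working-set selection,
   stopping at KKT violation < 1e-6 (cap 200 000 iterations).  The
   linear kernel lets decision values be maintained incrementally, so
   one iteration costs two matrix–vector products.  The offset b is the
   mean of the free-support-vector residuals (midpoint of the violation
   bounds if none are free).  Correctness is asserted by objective
   value — within 1e-4 relative of a reference convex optimum — not by
   iterate path.

LLSVM is restricted to binary problems (the motivating use case is
viable vs. apoptotic); LDA/QDA/KNN support any n_c ≥ 2.  A decision
value of exactly 0 maps to the first class.

## Model selection

- One initial stratified holdout (default test fraction 0.2 — not
  prescribed anywhere authoritative, chosen as the common default)
  separates D_MS from D_test; largest-remainder rounding keeps
  per-class proportions within one sample of the full table's.
- Stratified K-fold CV on D_MS, default K = 5 (standard bias/variance
  compromise at these sample sizes; no canonical value exists).  Fold
  assignment deals each class's shuffled members cyclically against a
  global pointer, so fold sizes differ by ≤ 1 overall *and* per class.
- Within each fold, scaler **and** filter ranking are refitted on the
  K−1 training subsets.  Refitting the ranking extends the stated
  leakage principle from scaling to every fitted parameter; a
  `per_fold_ranking=False` switch ranks once on all of D_MS instead,
  matching the common style of published n_FS sweeps.  Both modes are
  tested; the default is the stricter one.
- Grid search enumerates the Cartesian product of the grids the chosen
  classifier uses (n_FS always; k for KNN; C, γ, landmark count for
  LLSVM).  Random search draws discrete grids uniformly and C, γ
  log-uniformly between their grid extremes.  Default grids:
  n_FS ∈ {1, 2, 5, 10, 20, 50, all}, k ∈ {1, 3, 5, 11, 21, 51},
  C ∈ 2^{−5..15}, γ ∈ 2^{−15..3} (log step 2).
- Exact metric ties favor fewer features, then smaller k/C/γ, then
  grid order — simpler models win ties by design.
- Metric default is accuracy; when the training class ratio exceeds
  1:5 a log warning suggests the geometric mean, which is the
  appropriate selection metric under imbalance.

## Synthetic data: the stated world

`generate_population` draws labels i.i.d. from the class fractions and
builds features as:

- *informative*: unit-variance Gaussians, class means separated by
  `separation` σ (default 2.5, five such features) — the equal-prior
  Bayes accuracy is Φ(separation·√d / 2), giving the benchmark a
  closed-form ceiling (0.997 at the defaults);
- *redundant* (default 20): fixed nonnegative unit-norm mixtures of the
  informative block plus N(0, 0.1²) noise.  The mixing weights are
  drawn from a separate `structure_seed` so that every table of a
  kinetics or titration series shares one simulated "instrument";
- *noise* (default 75): independent standard Gaussians;
- optional *XOR pair*: jointly separable by the sign of the product,
  marginally class-symmetric — invisible to univariate filters;
- optional *heavy tail*: exponentiates all features (log-normal
  intensities).  The Bayes formula refers to the pre-transform scale.

Kinetics tables follow a logistic apoptotic fraction
1/(1 + e^{−slope·(t − t50)}) with defaults t50 = 60 min,
slope = 0.05 min⁻¹ over timepoints {0, 20, 40, 60, 120, 180} min,
matching a death-receptor stimulation course.  Titration tables use
exact deterministic label allocation (round(fraction · m) apoptotic).

Misleading dye channels reproduce two real failure modes.  The
*transient* kind (viability-dye-like) gives the apoptotic class a mean
that rises and then decays (dye leaking out of destroyed cells).  The
*early_switch* kind (executioner-caspase-like) switches cells to a
bright "on" distribution (6 σ above "off") along a logistic that leads
the class-defining kinetics by 30 min and is twice as steep — so the
nonstimulated endpoint is essentially dye-negative, the late endpoint
fully dye-positive (the channel looks excellent in end-point training),
yet intermediate timepoints overstate the apoptotic fraction.  The
doubled steepness is a generator choice: it makes the dye's endpoint
behaviour clean while preserving the mid-course lead that causes the
bias.

The class-imbalance fixture defaults to minority:majority = 1:100; the
ratio is a parameter, never a constant, because no authoritative value
exists for the motivating scenario.

**What a green test does not establish.**  The generator's features are
(transformed) Gaussians with independent noise; real IFC features have
arbitrary marginals, cell-cycle substructure, batch effects and
instrument drift.  Tests therefore establish algorithmic correctness
and the workflow's behaviour in a controlled world — not expected
accuracy on any real experiment.  Reported per-timepoint fractions
inherit the classifier's class-conditional error rates; they are
accurate here because the benchmark's Bayes error is small, not because
fraction estimation is bias-corrected (no abundance correction à la
classify-and-count adjustment is applied).

## Degenerate inputs and determinism

NaN/inf cells are rejected by default with the offending cells named;
an explicit flag drops affected rows and logs the count.  Duplicate or
empty feature names, unknown labels, single-member classes (where ≥ 2
are needed), and single-class SVM inputs all fail fast with specific
errors.  Every stochastic component (splits, folds, k-means, random
search, generators) is driven by an explicit integer seed;
series generators derive child seeds through `numpy.random.SeedSequence`
so each table is independently reproducible.  Models serialize to
versioned JSON at full float precision; a saved and reloaded model
produces bit-identical predictions.

## Known limitations

- No FCS or proprietary IFC container parsing — delimited text only.
- LLSVM is binary; no polynomial kernels; no probability calibration
  for KNN/SVM.
- No nested cross-validation: the test report is unbiased for the
  winning model, but repeated peeking at the same test set across many
  analyses would erode that guarantee.
- Wrapper/embedded feature selection and population-level abundance
  corrections are out of scope.
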