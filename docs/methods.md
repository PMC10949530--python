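# Methods

This note documents the statistical models, numerical choices and known
limitations of `mmgp`.  It is the design record: everything empirical stated
here is computed by the test suite or by `scripts/acceptance.py`.

## Genotype quality control (`genotype_io`)

Genotypes arrive in the TASSEL numeric coding (1 homozygous major, 0.5
heterozygous, 0 homozygous minor) and are recoded entrywise to dosage
deviations {−1, 0, +1} (minor-allele dosage minus one).  The recode is a
bijection on the three valid values; anything else is an error, never a
silent coercion.

Marker filters, in order:

1. **Missingness** — a marker with ≥ 50% missing calls (threshold
   configurable) is removed.  Running this first means MAF is computed only
   on markers with enough data, and a marker failing both rules is counted
   once, under missingness.  A marker with zero observed calls is removed
   here, never a division by zero.
2. **MAF** — minor-allele frequency `p = Σ dosage / (2·n_observed)` folded to
   `min(p, 1−p)`; markers with `p < 0.05` (configurable) are removed.  The
   dosage-count formula is our choice; the source material names the cutoff
   but not the estimator.

Mean imputation replaces each missing cell with its marker's observed mean,
exactly preserving per-marker means.  Filtering is idempotent and the QC
report satisfies `out = in − removed_maf − removed_missing` by construction
(both are property-tested).  Per-line filtering is deliberately not applied;
only markers are screened.

## Relationship matrix and network features (`kinship`)

G is VanRaden method 1: center marker columns, `G = W W′ / c` with
`c = Σ_k 2 p_k (1 − p_k)` on the dosage scale.  This construction is a
package choice — standard in the genomic-selection literature — and under it
`mean(diag G) ≈ 1` for panels in Hardy–Weinberg-ish equilibrium (checked by
simulation).  A diagonal jitter of `1e−6 · mean(diag G)` keeps G factorable
even with duplicated lines.

**Factor orientation.**  The textual convention writes `X_L = Z_L L_G` with
`G = L_G′ L_G` (upper factor), under which the feature Gram is
`L_G L_G′ ≠ G`.  The default here is the `gram` orientation — the lower
factor F with `F F′ = G` — because it makes the feature Grams reproduce the
mixed-model covariances exactly (`X_L X_L′ = Z_L G Z_L′`, and likewise for
the interaction block), i.e. a linear model on the features is precisely
GBLUP.  The literal upper-factor reading remains available
(`orientation="upper_GtLL"`); the choice affects a fixed orthogonal rotation
of the features, which matters to neither model family's covariance
structure.

The interaction block exploits `chol(I ⊗ G) = I ⊗ chol(G)` (verified densely
in tests): row (i, j) of `Z_EL (I ⊗ F)` is the factor row of line j placed in
environment i's column block, so memory scales with `n_obs · I · J` and the
`(I·J)²` interaction relationship matrix is never materialized (asserted with
an allocation guard).

## Bayesian GBLUP (`gblup`)

Model: `Y_ij = μ + E_i + g_j + gE_ij + ε_ij` with `g ~ N(0, σ_g² G)`,
`gE ~ N(0, σ_gE² (I ⊗ G))`, iid Gaussian residuals; flat priors on μ and
environment effects, scaled-inverse-χ² priors on variances.

- **Prior scales.**  `df0 = 5`, `R2 = 0.5`: the prior mode of each genetic
  variance is `var(y)·R2 / n_random_terms` and of the residual
  `var(y)·(1−R2)`, i.e. `S0 = mode·(df0+2)/df0`.  This mode-matching rule is
  one member of the family of equivalent conventions; both numbers are
  configurable.
- **Sampler.**  Blocked Gibbs: fixed effects jointly (treatment-coded
  contrasts to keep the design full-rank; effects re-expressed afterwards as
  μ plus sum-to-zero environment deviations); line effects in the eigenbasis
  of G (one symmetric eigendecomposition, reused); interaction effects
  blockwise per environment, reusing the same eigenbasis — the I ⊗ G
  structure makes the per-block precision `U′Z_i′Z_iU/σ_ε² + D⁻¹/σ_gE²`.
- **Chain defaults** 6000/1000/5 (iterations/burn-in/thin) are a desk-scale
  choice; at J = 300 with a complete 3-environment design a 3000-iteration
  chain recovers (σ_g², σ_gE², σ_ε²) = (1, 0.5, 1) within ±25% averaged over
  five replicates, and two chains with different seeds agree on posterior-mean
  predictions to < 2% relative RMS.
- **Oracle.**  `blup_closed_form` solves Henderson's equations exactly at
  fixed variance ratios; sampler and oracle predictions correlate > 0.999 at
  matched variances.  Limiting behavior (interpolation as σ_ε² → 0 with a
  tight residual prior, shrinkage to environment means as σ_g² → 0, zero
  effect for kinship-isolated lines) is tested.
- **Prediction** is `ŷ = μ̂ + Ê_i + ĝ_j + ĝE_ij` from posterior means,
  omitting any term not in the fitted predictor.  An environment unseen in
  training contributes 0 (the average environment under sum-to-zero coding).

## Multi-modal network (`mmdl`)

One residual-block stack per modality, concatenation, an optional fusion
stack, a single linear output neuron.  Block order:
`dense(L2) → BN → ReLU → dense(L2) → BN → (+ skip) → ReLU → dropout`, with a
linear projection on the skip path when widths change; batch normalization
always precedes the activation.  One hidden "layer level" equals one residual
block, so a depth of L_q means L_q blocks; widths follow
`N(l) = ⌊N(1)/2^(l−1)⌋` clamped to ≥ 1.  A fusion depth of 0 feeds the
concatenation straight to the output neuron.

Training: Adam on mean-squared error, L2 penalty λ on all dense weight
matrices (not biases or BN parameters), batches of 32, at most 48 epochs,
learning rate `lr₀·exp(−wd·epoch)`, early stopping when the training loss
fails to improve for `patience` consecutive epochs (a validation-monitoring
switch exists).  Responses are standardized on the training fold and
de-standardized at prediction, so learning-rate ranges assume O(1) targets.

The implementation is plain numpy with hand-written backpropagation.  Batch
membership is shuffled each epoch but rows within a batch are processed in
sorted order, which keeps floating-point reductions — and therefore whole
training runs — bit-reproducible for a fixed seed on one device.  Inference
uses running batch-norm statistics and no dropout, so predictions are
deterministic, independent of batch partitioning, and invariant to the
dropout rate.

The desk-scale capacity gate: a one-block, 64-unit network must overfit a
40-observation linear target to training MSE < 5% of var(y) within the
standard protocol.

## Hyperparameter search (`hyperopt`)

Search domain (defaults): modality depths (1,4)/(1,6)/(1,6); fusion depth
(0,4); first-layer widths (0,128)/(1,1024)/(1,1024); fusion width (0,200);
λ ∈ (1e−8, 1e−2); dropout ∈ (1e−4, 0.5); log weight decay ∈
(ln 4e−5, ln 4e−1); patience (0,128); log learning rate ∈ (ln 1e−8, ln 1e−2).
Integer dimensions are rounded then clamped (widths and patience to ≥ 1;
fusion depth may be 0 — a depth-0 fusion is a meaningful architecture);
log-scale dimensions are exponentiated.

The optimizer is a Matérn-5/2 Gaussian process with expected improvement,
inputs scaled to the unit cube, scores standardized, proposals taken as the
EI maximizer over a seeded Sobol candidate set; a budget of 50 counts *all*
evaluations, including the 10 quasi-random initial points.  A pure
random-search strategy with the same budget is the fast fallback.  On a 1-D
quadratic the GP loop localizes the minimum to < 0.05 with budget 50, and on
a separable 2-D objective it beats random search in a 20-seed sign test.

Inner validation: a seeded 10-fold partition of the training set, folds 1–2
(20%) scoring, folds 3–10 sub-training.  Per-trial epoch counts may be
reduced (`tune_epochs`) with the final refit at the full 48.

## Evaluation protocols (`evaluation`)

- **k-fold** — observations shuffled within environment and dealt round-robin,
  so folds are balanced globally (sizes differ ≤ 1) and stratified by
  environment.  `invert_roles` trains on one fold and tests on the rest
  (training fractions 1/k, for the data-size study); `repeats` re-randomizes
  with derived seeds.
- **LOEO** — one split per environment; the interaction predictor is refused
  (the held-out environment has no estimable interaction), and the network's
  unseen-environment one-hot is replaced by a uniform weight over training
  environments — the same average-environment convention the mixed model
  uses.
- **NRMSE** — RMSE divided by the mean of observed test values (the
  normalizer the benchmark tables are consistent with, for strictly positive
  traits); `range` and `sd` normalizers available.  A zero normalizer is an
  error suggesting an alternative, never a silent infinity.
- **Comparison** — win counts use strict inequality (ties favor neither
  model); relative differences are `100·(x/y − 1)` with the favored model in
  the numerator, matching how such results are customarily phrased.
  Hyperparameter summaries take the per-group mode for integer dimensions
  (smallest value on ties) and the mean for real ones.

## Synthetic trials (`synthetic`)

The generator draws exactly the mixed-model structure: marker dosages
Binomial(2, p) with p ~ U(0.1, 0.9); g through the triangular factor of the
marker-derived G; gE independently per environment with covariance σ_gE² G
(precisely I ⊗ G — no cross-environment genetic correlation, since the model
has none); random environment main effects (treated as fixed unknowns by the
fitters); iid Gaussian noise.  Effects are drawn in canonical (sorted) line
order, so relabeling marker rows is exactly invisible to the phenotypes.

Defaults are a desk-scale trial: J = 300 lines, I = 3 environments,
M = 2000 markers, (σ_g², σ_gE², σ_ε²) = (1.0, 0.5, 1.0), grand mean 10 (so
mean-normalized error is well defined), simulating and fitting in under a
minute.  The end-to-end comparison uses σ_ε² = 0.5, putting the realized
narrow-sense heritability — var(g) over within-environment phenotypic
variance — at ≈ 0.5.

What the generator does *not* emulate: linkage disequilibrium and haplotype
structure, dominance/epistasis, selection, trait-specific variance scales,
non-Gaussian residuals, and systematically unbalanced designs beyond random
phenotype dropout.  Passing tests therefore demonstrate correctness of the
machinery and sane behavior under the model's own assumptions, not
performance on real breeding data — on which the relative ranking of the two
model families can differ.

## Numerical choices and degenerate inputs

- Diagonal jitter `1e−6·mean(diag G)` before factorization; a failed
  factorization advises increasing it.
- Cholesky reconstruction tolerance 1e−8·‖G‖; symmetry enforced to 1e−10.
- Constant vectors make Pearson correlation an error, not 0.
- Monomorphic whole panels (c = 0) are an error in `compute_grm`.
- Non-finite training loss aborts with the epoch named.
- All randomness flows from per-call seeds through named `SeedSequence`
  substreams; nothing reads global RNG state.

## Known limitations

- The Gibbs sampler is single-trait and covers G-covariance random effects
  only (no marker-effect parameterizations, no REML point estimates).
- The network trains on CPU at desk scale; the study-scale inputs
  (thousands of lines, 8–15 h training runs) are out of scope.
- GP-EI proposals come from a finite Sobol candidate set, not a continuous
  acquisition optimizer; for ≤ 13 dimensions and 50-evaluation budgets this
  is adequate and much cheaper.
- The bundled benchmark tables are transcriptions used as aggregation
  oracles; reproducing the original tables' metric values themselves would
  require the restricted-access dataset and GPU-scale training.
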