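# Methods

## The problem

Bulk expression and DNA-methylation profiles from complex tissues are
mixtures of signals from multiple cell types. Writing the observed
features-by-samples matrix as **Y** (P × N), most deconvolution methods
seek a factorization

    Y = W H

where **W** (P × K) holds the pure profiles of K cell types and **H**
(K × N) the per-sample mixing proportions. Every column of **H** lies on
the unit simplex (nonnegative, summing to one); for methylation beta
values the entries of **W** are additionally bounded by 0 and 1.
Reference-free (RF) deconvolution estimates both factors from **Y** alone.

The quality of RF estimates depends strongly on which features enter the
factorization. Features are conventionally chosen by overall variance, but
observed variance mixes three sources: within-cell-type variation,
cross-cell-type mean differences, and mixing-proportion variability. Only
the cross-cell-type component helps; high within-type variance actively
misleads. This package implements an iterative scheme that replaces the
variance heuristic with model-driven marker selection.

## Cross-cell-type differential testing

Given proportions (estimated or known), the expected bulk level of feature
p is a proportion-weighted sum of per-cell-type means:

    E(Y_p) = V beta_p,

with V the N × K matrix of sample proportions and beta_p = (mu_p1, ...,
mu_pK). The model is fit per feature by ordinary least squares. Cell-type
specificity of feature p in type k is the one-vs-rest contrast

    H0:  mu_pk − (1/(K−1)) Σ_{i≠k} mu_pi = 0,

tested with a Wald t statistic, two-sided, on df = N − K. Numerical
choices:

- **Variance floor.** Some features produce near-zero residual variances
  and absurd t statistics. All per-feature variance estimates are raised
  to their empirical 10th quantile (linear interpolation between order
  statistics, so the 0.1 quantile of 1..10 is 1.9). If that quantile is
  exactly zero, a tiny positive fallback (1e-12 × max(1, max variance))
  keeps the statistics defined.
- **Negative means.** Fitted cell-type means can be negative even though
  they represent abundances. An option clamps them to zero before the
  contrast; residual variances are not recomputed (the clamp only shifts
  the contrast estimates). Disabled by default — in practice few
  coefficients are affected.
- **Reference distribution.** p-values use the Student t with N − K
  degrees of freedom rather than the normal; at the default N = 100,
  K = 4 the difference is minor.

Under a correctly specified null the test is well calibrated: at 10,000
features the fraction of p < 0.05 sits within a point of 0.05 and the
p-value distribution is uniform to Kolmogorov–Smirnov distance < 0.02
(checked in the test suite).

## The iterative refinement loop

1. Pick an initial feature list M0 (default: the 1001st–2000th most
   variable features; the top-1000 window and random lists are also
   supported). The second window is preferred because the very top of the
   variance ranking is the most contaminated by high within-type-variance
   features.
2. Deconvolve Y restricted to M0 (iteration 0, the baseline).
3. Iterate: with the latest proportion estimates, run the cross-cell-type
   test on the **whole** matrix; keep the top |M0| features (default
   1000), balanced across cell types; re-deconvolve on them from fresh
   random starts.
4. After `max_iter` iterations (default 30), return the iteration with
   the smallest reconstruction RMSE = sqrt(Σ(Y_sub − WH)² / (|M| N)).
   RMSE is observable without ground truth, and across iterations it is
   negatively associated with accuracy, which is what makes it a usable
   endpoint criterion. The baseline is excluded from the argmin: its RMSE
   is computed on a different feature list (typically with much larger
   values and variances) and is not comparable; ties resolve to the
   earliest iteration.

**Marker ranking.** The per-cell-type tests must be merged into one list
of `n_marker` features. Per type, features are ranked by ascending
p-value, ties broken by descending |contrast estimate| and then feature
ID; the per-type lists are merged round-robin in cell-type label order,
skipping features already taken. This balances marker counts across types
— a pooled p-value ranking would let a dominant, well-estimated type
crowd out minority types.

**Seeding.** Iteration t seeds its engine restarts from `seed + 1000·t`,
so runs are independent across iterations yet bit-reproducible. Each
iteration starts fresh rather than warm-starting from the previous
factors, treating the engine as a black box re-run per feature list.

## The factorization engine

Alternating constrained least squares:

- **H-step.** Per sample, minimize ‖y_s − W h‖² over the simplex. Solved
  *exactly* by enumerating the ≤ 2^K − 1 support sets: for each support
  the equality-constrained minimizer is a small KKT solve, and the best
  feasible support is the global optimum. Enumeration is vectorized
  across samples and exact, unlike penalty-term approximations.
- **W-step.** Per feature, minimize ‖y_p − Hᵀ w‖² subject to w ≥ 0 (and
  w ≤ 1 for methylation). Same enumeration idea over bound patterns
  (≤ 3^K), vectorized across features.

Because each half-step is an exact minimizer, the Frobenius objective is
non-increasing; iteration stops when its relative decrease falls below
`tol` (default 1e-6) or after `max_inner` sweeps (default 1000). The fit
restarts `n_restarts` times (default 3) from random initializations
(W ~ U(0, max Y), H columns ~ Dirichlet(1); restart r uses seed + r) and
returns the lowest-RMSE solution. A restart whose H has a collapsed row
(max < 1e-6) is discarded; if all collapse, the error advises lowering K.
K = 1 is handled analytically (H ≡ 1, W = row means).

The same solver drives the reference-based estimator (constrained least
squares of each sample on a known signature) — a deliberately plain RB
method without robust-regression refinements.

**Component alignment.** RF components are unlabeled. All
truth-comparisons first match components by maximizing the summed
per-type Pearson correlation over permutations (exhaustive for K ≤ 8,
which also makes ties resolve to the lexicographically smallest
permutation; Hungarian assignment above that). Zero-variance rows
contribute zero correlation to the matching and NaN (excluded, with a
warning) to reported means.

**Identifiability caveat.** On noiseless data with strictly positive
signatures and strictly interior proportions the factorization is not
unique — a small rotational ambiguity survives any optimizer. Exact
recovery is only a fair expectation when the samples cover the simplex
corners; the test fixtures therefore draw proportions from a sparse
Dirichlet(0.5).

## The synthetic-data generator

The generator produces the study conditions every stochastic test runs
under.

- **Pure panels.** Per subject, each feature × cell type value is drawn
  log-normally (expression) or normally clipped to [0, 1] (methylation)
  around per-feature, per-type locations and scales. Locations/scales can
  be estimated from replicated pure profiles or generated synthetically:
  baseline natural-log means ~ N(5, 1) shared across types; within-type
  log-sd drawn per feature, U(0.1, 0.8) for background and U(0.05, 0.2)
  for markers (good markers have low within-type variance — the premise
  of the whole method). Each of the K types owns `n_markers_per_type`
  planted markers (default 250, so K = 4 matches the default 1000-marker
  selection), shifted by `effect_lfc` in their own type — default 2.3
  natural-log units (~10-fold), the strong specificity typical of marker
  genes in purified immune profiles.
- **Correlated background variation.** Background features additionally
  load on two per-subject latent factors (loadings N(0, 0.1) on the log
  scale, N(0, 0.01) on the beta scale; markers load zero). Real
  within-type variation is not independent across features — co-expression
  modules and subject effects create low-rank structure that a
  variance-ranked feature list drags into the factorization, which is
  precisely why variance-selected features underperform. The factor
  strength is calibrated so the variance-window baseline reaches a mean
  truth-correlation of roughly 0.8 at N = 100, the regime where iterative
  re-selection visibly pays off without being trivial.
- **Mixing.** Proportions ~ Dirichlet(0.968, 4.706, 0.496, 0.347) for
  four types or (0.89, 4.12, 0.47, 0.33, 0.61, 1.02) for six — one
  dominant type, several minorities, as in whole blood. Mixing happens on
  the linear scale (the physical model behind Y = WH). Additive Gaussian
  measurement noise with default sd = 0.1 × the median per-feature panel
  sd; mixtures clip at 0 (and 1 for methylation).
- **RNA-seq counts.** Baseline log2 means ~ N(5, 2); each of
  `n_true_degs` planted DE genes belongs to one cell type with log2 fold
  change ~ N(0, 1.5) truncated to |lfc| ≥ 0.5; per-type expected counts
  are mixed by Dirichlet proportions, scaled by a U(0.7, 1.3) library
  factor, and drawn negative-binomially with dispersion 0.1
  (var = μ + 0.1 μ²). Testing happens on log2(library-size-normalized
  count + 1), which keeps the OLS mixture model applicable.

**What the generator does not emulate:** probe-level effects and
saturation of real arrays, batch structure, count noise in microarray
intensities, correlated *marker* variation, cell types absent from the
model, and proportions correlated with phenotype. Passing tests therefore
demonstrate the algorithmic properties — calibration, improvement from
iteration, endpoint behavior — under the stated statistical model, not
performance on any particular real dataset.

## Problem sizes in the shipped tests

The refinement batch in the acceptance-level tests runs 20 simulated
expression studies (P = 5000, K = 4, N = 100) with `max_iter` = 10,
2 engine restarts per fit and `max_inner` = 300 — at this sample size the
refinement has typically saturated by iteration 10, and a 20-replicate
paired comparison is sufficient to establish the improvement direction.
The RNA-seq evaluation uses the full 10,000 × 100 design. Single-instance
unit tests use small separable mixtures where expected results are exact.

## Known limitations

- K must be supplied; no model-selection criterion is provided.
- The engine is a generic alternating solver, not a re-implementation of
  any particular published RF package; solutions agree in the
  identifiable regime but are not byte-comparable.
- The RB estimator is plain constrained least squares (no robust
  weighting), so outlier features influence it fully.
- With very small sample sizes (N < 50) or many cell types the default 30
  iterations may be too few, and weak minority components (mean
  proportion ≲ 5%) can remain unidentifiable at realistic noise — more
  iterations and restarts help only partially.
- Support enumeration in the engine is exponential in K; it is intended
  for the usual K ≤ 10 regime.
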