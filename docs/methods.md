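# Methods

## Model

`mogpfa` fits a dynamic factor analysis model to sparse, irregular
longitudinal biomarker panels.  For subject *i*, biomarker *g* and visit time
*t_ij*,

    x_ijg = mu_ig + sum_a l_ga y_ia(t_ij) + e_ijg,     e_ijg ~ N(0, phi_g^2)

with `a = 1..k` latent factors.  Three structural assumptions carry the
method:

1. **Sparse loadings.**  Each loading is a point-mass mixture
   `l_ga = Z_ga A_ga` with `Z_ga ~ Bernoulli(pi_a)`, `pi_a ~ Beta(c0, d0)`,
   `A_ga ~ N(0, rho_a^2)`, `rho_a^2 ~ InvGamma(c1, d1)`.  Sparsity is exact:
   a biomarker either belongs to a factor or its loading is identically
   zero.  The default `c0 = 0.1 p`, `d0 = 0.9 p` encodes the expectation that
   each factor regulates ~10% of biomarkers.
2. **Cross-correlated smooth factor trajectories.**  The k factor
   trajectories jointly follow a multi-output Gaussian process constructed by
   kernel convolution: each factor is the sum of a Gaussian kernel
   `h(t) = v exp(-B t^2 / 2)` convolved against a *shared* white-noise base
   process (inducing cross-correlation), the same kernel family convolved
   against a factor-*specific* base process, and an i.i.d. nugget
   `eps_a(t) ~ N(0, psi^2)`.  The implied closed forms are

       auto:   C_aa(dt) = v_a0^2 sqrt(pi/B_a0) exp(-B_a0 dt^2/4)
                        + v_a1^2 sqrt(pi/B_a1) exp(-B_a1 dt^2/4)
                        + 1{dt=0} psi^2
       cross:  C_ab(dt) = v_a0 v_b0 sqrt(2 pi/(B_a0+B_b0))
                          exp(-(B_a0 B_b0/(B_a0+B_b0)) dt^2 / 2)

   both locked by an adaptive-quadrature oracle in the tests.  Zero-lag
   cross-correlations `rho_ab = C_ab(0)/sqrt(C_aa(0) C_bb(0))` are constant
   in time.  With a single shared base process the cross-correlation matrix
   is rank-one off the diagonal; the synthetic-data generator therefore also
   offers an explicit-correlation (i.i.d.-in-time) mode for truths that are
   not rank-one.
3. **Regularization for sparse sampling.**  Because 2–5 visits per subject
   cannot support an unconstrained GP, the factor means are constant but
   *non-zero* (`c_a`, estimated), and the kernel decay rates are penalized by
   `lambda * sum_a (B_a0 + B_a1)` — larger B means rougher trajectories, so
   the penalty favors smooth fits.

Identifiability: each factor's stationary variance `C_aa(0)` is constrained
to 1 (the scale is absorbed by the loadings), and the remaining
signed-permutation invariance (2^k k! relabelings) is resolved by
post-alignment (`align` module).

## Inference

Estimation is empirical-Bayes in two stages.

**Stage 1 — stochastic EM for (Theta, C).**  The marginal likelihood
integrates over all latent quantities and is intractable, so each EM
iteration replaces the E-step by a single draw: a block Gibbs chain is run at
the current hyperparameters (warm-started across iterations), one post-burn-in
draw of the factor scores on the *augmented* common grid (the union of all
subjects' visit times) is taken uniformly at random, and the M-step maximizes
the penalized common-grid MVN log-likelihood of that draw by L-BFGS-B.  The
common grid lets one Cholesky factorization serve all subjects, so the M-step
costs O(n k^2 q^2).  The iterates form a homogeneous Markov chain; the
estimate is the average of the last `m` iterates in the transformed parameter
space (log decay rates, variance-share logits, raw means), which keeps the
average feasible.

The M-step parameterization enforces unit variance by construction: per
factor, `(ln B_a0, ln B_a1, gamma_a)` where the shared-component share of the
non-nugget variance is `gamma_a^2/(1+gamma_a^2)` and `sign(gamma_a)` carries
the sign of the shared amplitude (hence of cross-correlations); a single
logit-parameterized nugget share is common to all factors.  The constant
means `C` have a closed-form GLS profile solution evaluated inside every
objective call.

Two practical safeguards proved essential and are part of the design:

* **Labeling coherence.**  The S-step chain can swap factor labels or flip
  signs between iterations; averaging transformed parameters across such
  flips annihilates the cross-correlation estimate.  Every iteration the
  picked draw, the chain state and the M-step warm start are re-aligned to a
  running loading reference by exhaustive signed-permutation search.
* **Data-driven chain initialization.**  Short S-step chains started from
  diffuse prior draws can lodge in rotated, over-dense local modes.  The
  chain starts instead from a truncated SVD of the centered panel, varimax-
  rotated toward the sparse mode, with scores obtained by regression on the
  *sparsified* loadings (regression on the full rotated basis would return
  exactly orthogonal scores, erasing the cross-correlations the model is
  meant to estimate).  `stem_fit` also moment-matches the starting
  hyperparameters by one M-step on these initialization scores.

**Stage 2 — block Gibbs for everything else.**  With (Theta, C) frozen, all
full conditionals are conjugate.  Loadings use a collapsed update: `Z_ga` is
drawn with `A_ga` integrated out analytically (avoiding the absorbing-state
pathology of naive two-step updates), vectorized across biomarkers, which are
conditionally independent.  Each subject's augmented scores are drawn as a
block in two stages: the scores at the subject's own visit times from their
MVN full conditional given the data, then the remaining grid times from the
MOGP conditional.  Subjects sharing a visit pattern share one Cholesky per
sweep.  `rho_a^2` conditions on the full `A` column, including spike rows
refreshed from the prior (switchable in principle; documented here so the
Z=1-only variant is a one-line change).  Every conditional is checked against
quadrature / joint-Gaussian / Geweke oracles in the tests.

**Posterior predictive.**  Biomarker trajectories on an arbitrary grid are
reconstructed per retained draw as `mu_ig + sum_a l_ga y_ia(t*)`, with scores
at off-grid times drawn from the MOGP conditional; pointwise medians and
2.5/97.5 percentiles form the band.  Observation noise is optional.

## Penalty selection

`lambda` is chosen on the grid `exp(-4), exp(-3.5), ..., exp(4)` (17 values,
0.02–54.60) by subject-level l-fold cross-validation (default l = 5).  For
each fold, hyperparameters are re-fitted on the training subjects; for each
test subject one randomly chosen visit is held out and its biomarker values
are predicted from the subject's *remaining* visits under the frozen
hyperparameters (leave-one-time-out; predicting from the prior mean alone
would make lambda nearly irrelevant).  The selected lambda minimizes the
fold-averaged mean absolute error.  Inside CV, reduced EM run lengths are
used and logged.

## Preprocessing

* **Age regression-out:** per biomarker, pooled OLS of the measurement on
  intercept + subject age; residuals (exactly uncorrelated with age) feed the
  factor model.  Constant age is rejected as rank-deficient.
* **Reference-grid coarsening:** each visit time maps to the nearest
  reference time (ties to the earlier one); within-subject collisions keep
  the earlier visit and log the drop.  The map reports per-subject shift
  standard deviations — under a stationary covariance an approximately
  constant per-subject shift is harmless, and the diagnostic quantifies how
  far a given panel is from that ideal.

## Synthetic data

Two designs ship with known truth.  The *regular benchmark*: k=4 factors,
p=100 biomarkers, q_i=8 common visit times (integer days 0–7), each factor
regulating ~10% of biomarkers with loadings ~ N(4, 1), grand means equally
spaced in [4, 16], sigma_g = phi_g = 0.5, and a positive-definite default
cross-correlation matrix (pairwise 0.6/0.3/0.1); scores are i.i.d. across
time from that matrix by default, or drawn from a CP-MOGP when temporal
smoothness is wanted.  The *irregular design*: n=101 subjects, p=35
biomarkers, 2–5 integer-day visits in 0–49 with about half the subjects
observed only twice.  Neither emulates real metabolite marginal
distributions, outliers, missing-biomarker visits, or informative visit
timing — passing recovery tests therefore demonstrates correctness of the
machinery under the stated generative conditions, not robustness to those
real-data features.

## Numerical choices

* Cholesky factorizations retry once with jitter `1e-8 * mean(diag)` and then
  raise; sampling paths use a dense Cholesky (never the opaque LAPACK factor
  storage).
* M-step bounds: `|ln B| <= 12`, `|gamma| <= 30`, nugget logit in [-12, 6];
  gradient by finite differences; default cap of 40–60 L-BFGS iterations per
  M-step (a truncated M-step still satisfies the ascent guard below).
* The M-step returns the best point *evaluated*, so the objective never
  degrades relative to the warm start; an optimizer failure flags the
  iteration and the previous hyperparameters are reused.
* Initial hyperparameters: shared-component correlation halves at a quarter
  of the observed time span; equal shared/specific/nugget shares; zero means.
* Exact half-distance ties in grid coarsening resolve to the earlier time.

## Problem sizes used in the shipped checks

The recovery benchmark shipped in the tests and the acceptance script runs
the reduced design p=30, k=2, q_i=8, truth rho=0.6, lambda=0, 30 EM
iterations (last 10 averaged), 60-sweep S-step chains, at n in {10, 50, 100}
with 16–20 replicates; these sizes are the package's own scaled benchmark
design.  At p=30 with E[pi]=0.1, a replicate occasionally draws a factor that
regulates 0–1 biomarkers; its cross-correlation is then fundamentally
unidentifiable and such replicates legitimately populate the upper tail of
the MAD distribution (medians are reported for exactly this reason).

## Known limitations

* Every visit must record all p biomarkers; missing-biomarker visits are not
  modeled.
* One shared base process per factor set: rank-one cross-correlation
  structure in the MOGP mode (arbitrary matrices are available in the
  i.i.d. generator mode and, as estimands, only pairwise correlations are
  reported).
* k is pre-specified; compare several k in practice.
* No outcome/survival coupling; no non-Gaussian observation noise; no
  variational or inducing-point approximations for very large k q.
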