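# mogpfa

Dynamic factor analysis for **sparse, irregular longitudinal biomarker
panels** — e.g., metabolite measurements collected 2–5 times per patient at
scattered days over a follow-up window.

Biomedical pathways rarely act independently, and biomarkers rarely act
alone.  `mogpfa` maps p observed biomarkers onto a small number k of latent
factor trajectories ("pathway activities") while

* enforcing **exact sparsity** of the biomarker–factor loadings through a
  spike-and-slab (point-mass mixture) prior, so each factor names its member
  biomarkers without ad-hoc thresholds;
* letting factors be **cross-correlated over time** through a multi-output
  Gaussian process built by kernel convolution — a base process shared
  between factors induces the correlation, factor-specific processes capture
  the rest;
* staying stable under **very sparse sampling** via constant non-zero factor
  means and a roughness penalty `lambda * sum_a (B_a0 + B_a1)` on the kernel
  decay rates, with `lambda` chosen by subject-level cross-validation.

The model, for subject i, biomarker g, visit time t_ij:

    x_ijg = mu_ig + sum_a l_ga y_ia(t_ij) + e_ijg,   e_ijg ~ N(0, phi_g^2)
    l_ga  = Z_ga A_ga,      Z_ga ~ Bern(pi_a),   A_ga ~ N(0, rho_a^2)
    (y_i1, ..., y_ik) ~ MOGP with constant means c_a and convolution kernels
                        h(t) = v exp(-B t^2 / 2)

MOGP hyperparameters are estimated by a **stochastic EM** algorithm (one
Gibbs draw per E-step, penalized L-BFGS M-step on a common augmented time
grid); everything else is sampled by a **block Gibbs sampler**, with
signed-permutation alignment handling the label-switching/sign-flip
non-identifiability.  See `docs/methods.md` for the full account.

## Worked example

Simulate a panel with two cross-correlated factors (true rho = 0.6), fit the
hyperparameters, then sample the posterior of the loadings:

```python
import numpy as np
from mogpfa import (
    SimConfig, generate, stem_fit, StemConfig, run_gibbs, GibbsConfig,
    PriorConfig, align_draws, align_to_truth,
)
from mogpfa.kernel import cross_correlation_matrix

truth_corr = np.array([[1.0, 0.6], [0.6, 1.0]])
data = generate(SimConfig(n=50, p=30, k=2, correlation=truth_corr), seed=7)
panel = data.panel

theta, trace = stem_fit(
    panel, k=2, lam=0.0,
    stem_config=StemConfig(n_iters=30, m=10, s_chain_len=60), seed=1,
)
rho_hat = cross_correlation_matrix(theta)
print("estimated cross-correlation:", round(rho_hat[0, 1], 3))

sp, mad = align_to_truth(None, rho_hat, None, data.truth.correlation, k=2)
print("truth-aligned MAD:", round(mad, 3))

priors = PriorConfig.default(panel)
samples = run_gibbs(panel, theta, priors, GibbsConfig(n_iter=2000, thin=4, seed=1))
align_draws(samples)
L = samples.stacked("L")
g = int(np.abs(data.truth.L[:, 0]).argmax())
med, (lo, hi) = np.median(L[:, g, 0]), np.percentile(L[:, g, 0], [2.5, 97.5])
print(f"loading of {panel.biomarkers[g]} on factor 1: "
      f"{med:.2f} (95% CI {lo:.2f}, {hi:.2f})")
```

Output:

```
estimated cross-correlation: 0.603
truth-aligned MAD: 0.003
loading of B012 on factor 1: 4.34 (95% CI 4.10, 4.62)
```

The estimated zero-lag factor cross-correlation (0.603) recovers the
generating value 0.6; the MAD is the mean absolute difference between
estimated and true cross-correlations after searching all 2^k k! signed
permutations of the factors.  The loading posterior gives a point estimate
and credible interval for how strongly a biomarker participates in a factor
(the generating loading here was 4.67; loadings are on the scale fixed by
the unit-variance factor normalization).

The same workflow is available from the shell:

```bash
mogpfa simulate --design covid-like --seed 1 --out sim/
mogpfa fit --input sim/panel.csv --k 2 --lam 1.0 --iters 200 --out fit/
mogpfa cv-lambda --input sim/panel.csv --k 2 --out cv/
mogpfa sample --input sim/panel.csv --theta fit/theta.json --iters 10000 --out post/
mogpfa predict --input sim/panel.csv --theta fit/theta.json \
    --subject S000 --biomarker B009 --out pred.csv
mogpfa preprocess --input panel.csv --ages ages.csv --ref-grid 0,7,14,21,28,35,42,49 \
    --out prep.csv
```

`covid-like` generates an irregular design shaped like a COVID-19 metabolite
study (101 subjects, 35 biomarkers, 2–5 visits on integer days 0–49);
`preprocess` covers per-biomarker age regression-out and reference-grid
coarsening.

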