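"""Block Gibbs sampler for all unknowns except the MOGP hyperparameters.

Conditional on fixed hyperparameters (Theta, C), every full conditional of
Omega_aug = {M, Y_aug, A, Z, rho, pi, sigma, phi} is available in closed form
by conjugacy:

* subject-biomarker means mu_ig: Normal (prior N(mu_g, sigma_g^2) times the
  Gaussian likelihood of the factor-adjusted residuals);
* sigma_g^2, phi_g^2, rho_a^2: Inverse-Gamma; pi_a: Beta;
* loadings: per (g, a) a collapsed update -- the inclusion indicator Z_ga is
  drawn with the slab coefficient A_ga integrated out analytically, then A_ga
  is drawn from its Normal full conditional (slab) or refreshed from its prior
  (spike);
* factor scores: a two-stage block update per subject -- vec(Y_i^T) on the
  subject's observed times from its MVN full conditional given the data, then
  the scores at the remaining grid times from the MOGP conditional MVN.

Each conditional is verified against brute-force oracles (quadrature /
joint-Gaussian conditioning / a Geweke joint-distribution check) in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import expit, logit

from . import kernel
from .model import BiomarkerPanel, LatentState, PriorConfig, observation_loglik

__all__ = [
    "GibbsConfig",
    "PosteriorSamples",
    "run_gibbs",
    "gibbs_sweep",
    "update_means_and_noise",
    "update_loadings",
    "update_factor_block",
    "posterior_predictive",
]


@dataclass(frozen=True)
class GibbsConfig:
    n_iter: int = 2000
    burn_in_frac: float = 0.2
    thin: int = 1
    n_chains: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0.0 <= self.burn_in_frac < 1.0:
            raise ValueError("burn_in_frac must be in [0, 1)")
        if self.n_iter <= self.n_burn:
            raise ValueError("n_iter must exceed the burn-in length")

    @property
    def n_burn(self) -> int:
        return int(self.burn_in_frac * self.n_iter)


class PosteriorSamples:
    """Retained draws per chain, with optional alignment metadata.

    ``chains`` is a list (one entry per chain) of dicts mapping field name
    (``"L"``, ``"A"``, ``"Z"``, ``"M"``, ``"Yaug"``, ``"pi"``, ``"rho2"``,
    ``"sigma2"``, ``"phi2"``, ``"loglik"``) to arrays whose first axis indexes
    draws.
    """

    def __init__(self, chains, aligned: bool = False, alignments=None):
        self.chains = chains
        self.aligned = aligned
        self.alignments = alignments

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def n_draws(self, chain: int = 0) -> int:
        return self.chains[chain]["L"].shape[0]

    def stacked(self, name: str) -> np.ndarray:
        """All chains' draws of one field concatenated along the draw axis."""
        return np.concatenate([c[name] for c in self.chains], axis=0)

    def loadings_frame(self, biomarkers=None):
        """Long-format loading draws with chain/draw indices (columnar store)."""
        import pandas as pd

        rows = []
        for c, chain in enumerate(self.chains):
            n_draws, p, k = chain["L"].shape
            for d in range(n_draws):
                for g in range(p):
                    name = biomarkers[g] if biomarkers is not None else g
                    for a in range(k):
                        rows.append((c, d, name, a, chain["L"][d, g, a]))
        return pd.DataFrame(rows, columns=["chain", "draw", "biomarker",
                                           "factor", "loading"])

    def scores_frame(self, subjects=None, grid=None):
        """Long-format factor-score draws with chain/draw indices."""
        import pandas as pd

        rows = []
        for c, chain in enumerate(self.chains):
            n_draws, n, k, q = chain["Yaug"].shape
            for d in range(n_draws):
                for i in range(n):
                    sid = subjects[i] if subjects is not None else i
                    for a in range(k):
                        for j in range(q):
                            t = grid[j] if grid is not None else j
                            rows.append((c, d, sid, a, t,
                                         chain["Yaug"][d, i, a, j]))
        return pd.DataFrame(rows, columns=["chain", "draw", "subject",
                                           "factor", "time", "score"])


# ---------------------------------------------------------------------------
# caches


class _PanelCache:
    """Concatenated observation arrays for vectorized sweeps."""

    def __init__(self, panel: BiomarkerPanel):
        self.qi = panel.q_i
        self.N = int(self.qi.sum())
        self.Xcat = np.concatenate(panel.X, axis=1)          # p x N
        self.subj_of_obs = np.repeat(np.arange(panel.n), self.qi)
        self.grid_of_obs = np.concatenate(panel.obs_idx)
        self.starts = np.concatenate([[0], np.cumsum(self.qi)[:-1]])

    def ycat(self, Yaug: np.ndarray) -> np.ndarray:
        """Factor scores gathered at every observation, k x N."""
        return Yaug[self.subj_of_obs, :, self.grid_of_obs].T

    def subject_sums(self, arr: np.ndarray) -> np.ndarray:
        """Sum an (p x N) array over each subject's observations -> n x p."""
        return np.add.reduceat(arr, self.starts, axis=1).T


class _PatternOps:
    """Precomputed operators for one observation-time pattern (grid indices)."""

    def __init__(self, sigma_aug, mean_aug, obs_idx, k, q):
        obs_idx = np.asarray(obs_idx, dtype=int)
        qi = obs_idx.size
        self.qi = qi
        self.idx_obs = (np.arange(k)[:, None] * q + obs_idx[None, :]).ravel()
        add = np.setdiff1d(np.arange(q), obs_idx)
        self.idx_add = (np.arange(k)[:, None] * q + add[None, :]).ravel()
        self.add_grid = add
        self.obs_grid = obs_idx
        self.m_obs = mean_aug[self.idx_obs]
        if qi == 0:
            # no data: the full conditional is the MOGP prior on the grid
            self.A_cond = None
            self.K_inv = np.zeros((0, 0))
            self.prior_chol = _chol_dense(sigma_aug)
            self.m_add = mean_aug
            return
        s_oo = sigma_aug[np.ix_(self.idx_obs, self.idx_obs)]
        c_oo = _chol(s_oo)
        self.K_inv = cho_solve(c_oo, np.eye(self.idx_obs.size))
        if self.idx_add.size:
            s_ao = sigma_aug[np.ix_(self.idx_add, self.idx_obs)]
            self.A_cond = s_ao @ self.K_inv
            cov_cond = sigma_aug[np.ix_(self.idx_add, self.idx_add)] - self.A_cond @ s_ao.T
            self.chol_cond = _chol_dense(cov_cond)
            self.m_add = mean_aug[self.idx_add]
        else:
            self.A_cond = None


class FactorBlockCache:
    """Per-(Theta, panel) precomputation shared by all factor-block updates."""

    def __init__(self, theta: kernel.MOGPHyperparams, panel: BiomarkerPanel):
        self.theta = theta
        self.k = theta.k
        self.q = panel.q
        self.sigma_aug = kernel.build_covariance(theta, panel.grid)
        self.mean_aug = kernel.mean_vector(theta, panel.q)
        self.chol_aug = _chol(self.sigma_aug)
        self.patterns: dict[tuple, _PatternOps] = {}
        self.groups: dict[tuple, list[int]] = {}
        for i, ix in enumerate(panel.obs_idx):
            key = tuple(ix.tolist())
            if key not in self.patterns:
                self.patterns[key] = _PatternOps(
                    self.sigma_aug, self.mean_aug, ix, self.k, self.q
                )
                self.groups[key] = []
            self.groups[key].append(i)
        self.subject_key = [tuple(ix.tolist()) for ix in panel.obs_idx]


def _chol(cov: np.ndarray):
    """Factorization for solves (cho_solve) with a single jittered retry."""
    try:
        return cho_factor(cov, lower=True)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * float(np.mean(np.diag(cov)))
        return cho_factor(cov + jitter * np.eye(cov.shape[0]), lower=True)


def _chol_dense(cov: np.ndarray) -> np.ndarray:
    """Dense lower-triangular Cholesky factor (for sampling), jittered retry."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * max(float(np.mean(np.diag(cov))), 1e-30)
        return np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))


# ---------------------------------------------------------------------------
# full-conditional updates


def update_means_and_noise(
    state: LatentState,
    panel: BiomarkerPanel,
    priors: PriorConfig,
    rng: np.random.Generator,
    cache: _PanelCache | None = None,
) -> LatentState:
    """Draw M, sigma_g^2 and phi_g^2 from their full conditionals (in place)."""
    pc = cache or _PanelCache(panel)
    n, p = panel.n, panel.p
    mu_g = priors.mu_g if priors.mu_g.size else np.zeros(p)
    Ycat = pc.ycat(state.Yaug)
    R0 = pc.Xcat - state.L @ Ycat                       # x - L y, p x N
    S = pc.subject_sums(R0)                              # n x p
    prec = 1.0 / state.sigma2[None, :] + pc.qi[:, None] / state.phi2[None, :]
    mean = (mu_g[None, :] / state.sigma2[None, :] + S / state.phi2[None, :]) / prec
    state.M = mean + rng.standard_normal((n, p)) / np.sqrt(prec)

    state.sigma2 = _draw_invgamma(
        rng, priors.c2 + 0.5 * n, priors.d2 + 0.5 * ((state.M - mu_g[None, :]) ** 2).sum(0)
    )
    resid = R0 - state.M[pc.subj_of_obs].T
    state.phi2 = _draw_invgamma(
        rng, priors.c3 + 0.5 * pc.N, priors.d3 + 0.5 * (resid**2).sum(1)
    )
    return state


def _draw_invgamma(rng, shape, rate):
    return 1.0 / rng.gamma(shape, 1.0 / np.asarray(rate, dtype=float))


def update_loadings(
    state: LatentState,
    panel: BiomarkerPanel,
    priors: PriorConfig,
    rng: np.random.Generator,
    cache: _PanelCache | None = None,
) -> LatentState:
    """Draw Z, A (collapsed per factor), then pi and rho^2 (in place).

    For each factor a (all biomarkers vectorized, which are conditionally
    independent), the inclusion odds multiply the prior odds pi_a/(1-pi_a) by
    the ratio of marginal likelihoods with the slab coefficient integrated
    out; accumulation is in log space.
    """
    pc = cache or _PanelCache(panel)
    p, k = state.A.shape
    Ycat = pc.ycat(state.Yaug)
    E = pc.Xcat - state.M[pc.subj_of_obs].T - state.L @ Ycat
    Z, A = state.Z, state.A
    for a in range(k):
        ya = Ycat[a]
        la = A[:, a] * Z[:, a]
        Ra = E + np.outer(la, ya)                       # residual excluding factor a
        Syy = float(ya @ ya)
        Sry = Ra @ ya
        P = 1.0 / state.rho2[a] + Syy / state.phi2
        m = Sry / state.phi2 / P
        log_odds = logit(state.pi[a]) - 0.5 * np.log(state.rho2[a] * P) + 0.5 * m**2 * P
        Z[:, a] = (rng.random(p) < expit(log_odds)).astype(int)
        u = rng.standard_normal(p)
        A[:, a] = np.where(
            Z[:, a] == 1, m + u / np.sqrt(P), u * np.sqrt(state.rho2[a])
        )
        E = Ra - np.outer(A[:, a] * Z[:, a], ya)
    counts = Z.sum(axis=0)
    state.pi = rng.beta(priors.c0 + counts, priors.d0 + p - counts)
    state.rho2 = _draw_invgamma(
        rng, priors.c1 + 0.5 * p, priors.d1 + 0.5 * (A**2).sum(axis=0)
    )
    return state


def _update_factor_group(state, panel, cache, key, subjects, rng):
    """Two-stage block draw of Y_aug for all subjects sharing one time pattern."""
    ops = cache.patterns[key]
    k, q, qi = cache.k, cache.q, ops.qi
    if qi == 0:
        z = rng.standard_normal((k * q, len(subjects)))
        draws = cache.mean_aug[:, None] + ops.prior_chol @ z
        for col, i in enumerate(subjects):
            state.Yaug[i] = draws[:, col].reshape(k, q)
        return
    G = (state.L / state.phi2[:, None]).T @ state.L     # k x k likelihood precision/time
    Q = ops.K_inv.copy()
    ar = np.arange(qi)
    for a in range(k):
        for b in range(k):
            Q[a * qi + ar, b * qi + ar] += G[a, b]
    cQ = _chol(Q)
    prior_term = ops.K_inv @ ops.m_obs
    B = np.empty((k * qi, len(subjects)))
    for col, i in enumerate(subjects):
        resid = (panel.X[i] - state.M[i][:, None]) / state.phi2[:, None]
        B[:, col] = (state.L.T @ resid).ravel()
    mean = cho_solve(cQ, prior_term[:, None] + B)
    z = rng.standard_normal(mean.shape)
    y_obs = mean + solve_triangular(cQ[0].T, z, lower=False)
    if ops.A_cond is not None:
        z2 = rng.standard_normal((ops.idx_add.size, len(subjects)))
        y_add = (
            ops.m_add[:, None]
            + ops.A_cond @ (y_obs - ops.m_obs[:, None])
            + ops.chol_cond @ z2
        )
    for col, i in enumerate(subjects):
        flat = state.Yaug[i].reshape(k * q)
        flat[ops.idx_obs] = y_obs[:, col]
        if ops.A_cond is not None:
            flat[ops.idx_add] = y_add[:, col]


def update_factor_block(
    state: LatentState,
    panel: BiomarkerPanel,
    cache: FactorBlockCache,
    i: int,
    rng: np.random.Generator,
) -> LatentState:
    """Draw subject i's augmented factor scores from their full conditional."""
    try:
        _update_factor_group(state, panel, cache, cache.subject_key[i], [i], rng)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"Cholesky failure in factor block of subject {panel.subjects[i]}"
        ) from err
    return state


def update_factors(state, panel, cache, rng):
    """Factor-block update for every subject, grouped by observation pattern."""
    for key, subjects in cache.groups.items():
        _update_factor_group(state, panel, cache, key, subjects, rng)
    return state


def gibbs_sweep(state, panel, priors, fcache, pcache, rng):
    """One systematic scan: means/noise -> loadings -> factor blocks."""
    update_means_and_noise(state, panel, priors, rng, pcache)
    update_loadings(state, panel, priors, rng, pcache)
    update_factors(state, panel, fcache, rng)
    return state


# ---------------------------------------------------------------------------
# initialization and the main driver


def init_state_from_prior(
    panel: BiomarkerPanel,
    k: int,
    priors: PriorConfig,
    theta: kernel.MOGPHyperparams,
    rng: np.random.Generator,
) -> LatentState:
    """Draw a complete latent state from the prior (used to start chains)."""
    n, p, q = panel.n, panel.p, panel.q
    mu_g = priors.mu_g if priors.mu_g.size else np.zeros(p)
    pi = rng.beta(priors.c0, priors.d0, size=k)
    rho2 = _draw_invgamma(rng, priors.c1, np.full(k, priors.d1))
    sigma2 = _draw_invgamma(rng, priors.c2, np.full(p, priors.d2))
    phi2 = _draw_invgamma(rng, priors.c3, np.full(p, priors.d3))
    Z = (rng.random((p, k)) < pi[None, :]).astype(int)
    A = rng.standard_normal((p, k)) * np.sqrt(rho2)[None, :]
    M = mu_g[None, :] + rng.standard_normal((n, p)) * np.sqrt(sigma2)[None, :]
    chol = _chol_dense(kernel.build_covariance(theta, panel.grid))
    mean = kernel.mean_vector(theta, q)
    Yaug = (mean[:, None] + chol @ rng.standard_normal((k * q, n))).T.reshape(n, k, q)
    return LatentState(A=A, Z=Z, M=M, Yaug=Yaug, pi=pi, rho2=rho2,
                       sigma2=sigma2, phi2=phi2)


def init_state_data_driven(
    panel: BiomarkerPanel,
    k: int,
    priors: PriorConfig,
    theta: kernel.MOGPHyperparams,
    rng: np.random.Generator,
    jitter: float = 0.05,
) -> LatentState:
    """Initialize the chain near the data mode via a truncated SVD.

    The centered observation matrix is factored as L Y with unit-variance
    score rows; the sparsity pattern starts from thresholding the SVD
    loadings.  A small random jitter decorrelates parallel chains.  Starting
    near the dominant factor mode avoids the rotated, over-dense local modes
    a short chain can get trapped in when started from a diffuse prior draw.
    """
    pc = _PanelCache(panel)
    n, p, q = panel.n, panel.p, panel.q
    mu_g = priors.mu_g if priors.mu_g.size else panel.biomarker_means()
    Xc = pc.Xcat - mu_g[:, None]
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rootN = np.sqrt(pc.N)
    L0 = U[:, :k] * s[:k][None, :] / rootN
    # rotate toward the sparse loading mode; regression scores then retain
    # whatever cross-correlation the data imply (varimax scores would not)
    L0 = _varimax(L0)
    L0 *= np.sign(L0.sum(axis=0) + 1e-12)[None, :]
    Z = (np.abs(L0) > 0.5 * np.abs(L0).max(axis=0, keepdims=True)).astype(int)
    # regress on the *sparsified* loadings: scores on the full rotated basis
    # would be exactly orthogonal, erasing the factor cross-correlations
    Y0, *_ = np.linalg.lstsq(L0 * Z, Xc, rcond=None)
    sd = np.maximum(Y0.std(axis=1), 1e-6)
    Y0 /= sd[:, None]
    L0 *= sd[None, :]
    L0 = L0 + jitter * rng.standard_normal(L0.shape)
    Y0 = Y0 + jitter * rng.standard_normal(Y0.shape)
    A = np.array(L0)
    Yaug = np.zeros((n, k, q))
    for i in range(n):
        cols = slice(pc.starts[i], pc.starts[i] + pc.qi[i])
        Yaug[i][:, panel.obs_idx[i]] = Y0[:, cols]
    resid = Xc - (A * Z) @ Y0
    M0 = mu_g[None, :] + pc.subject_sums(resid) / pc.qi[:, None]
    resid = resid - (M0[pc.subj_of_obs].T - mu_g[:, None])
    phi2 = np.maximum(resid.var(axis=1), 1e-3)
    sigma2 = np.maximum((M0 - mu_g[None, :]).var(axis=0), 1e-3)
    counts = Z.sum(axis=0)
    pi = np.clip((priors.c0 + counts) / (priors.c0 + priors.d0 + p), 1e-3, 1 - 1e-3)
    rho2 = np.maximum((A**2 * Z).sum(axis=0) / np.maximum(counts, 1), 0.1)
    return LatentState(A=A, Z=Z, M=M0, Yaug=Yaug, pi=pi, rho2=rho2,
                       sigma2=sigma2, phi2=phi2)


def _varimax(L: np.ndarray, tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Orthogonal varimax rotation maximizing loading-variance simplicity."""
    p, k = L.shape
    if k == 1:
        return np.array(L)
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, sv, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr * ((Lr**2).sum(axis=0) / p)[None, :])
        )
        R = u @ vt
        d_new = sv.sum()
        if d_new <= d * (1 + tol):
            break
        d = d_new
    return L @ R


def sample_observations(panel: BiomarkerPanel, state: LatentState, rng) -> list[np.ndarray]:
    """Draw a replicate dataset X | Omega (used by joint-distribution checks)."""
    from .model import model_mean

    out = []
    for i in range(panel.n):
        mean = model_mean(state, panel, i)
        out.append(mean + rng.standard_normal(mean.shape) * np.sqrt(state.phi2)[:, None])
    return out


_RECORD_FIELDS = ("A", "Z", "M", "Yaug", "pi", "rho2", "sigma2", "phi2")


def run_gibbs(
    panel: BiomarkerPanel,
    theta: kernel.MOGPHyperparams,
    priors: PriorConfig,
    config: GibbsConfig,
    init_state: LatentState | None = None,
) -> PosteriorSamples:
    """Run one or more Gibbs chains and return burn-in-trimmed, thinned draws.

    Chain seeds derive deterministically from ``config.seed`` via
    ``SeedSequence.spawn``, so identical configurations reproduce identical
    sample sequences.
    """
    fcache = FactorBlockCache(theta, panel)
    pcache = _PanelCache(panel)
    chains = []
    for child in np.random.SeedSequence(config.seed).spawn(config.n_chains):
        rng = np.random.default_rng(child)
        state = init_state.copy() if init_state is not None else init_state_from_prior(
            panel, theta.k, priors, theta, rng
        )
        records: dict[str, list] = {f: [] for f in _RECORD_FIELDS}
        records["L"] = []
        records["loglik"] = []
        for it in range(config.n_iter):
            gibbs_sweep(state, panel, priors, fcache, pcache, rng)
            if it >= config.n_burn and (it - config.n_burn) % config.thin == 0:
                for f in _RECORD_FIELDS:
                    records[f].append(np.array(getattr(state, f)))
                records["L"].append(state.L)
                records["loglik"].append(observation_loglik(panel, state))
        chains.append({f: np.array(v) for f, v in records.items()})
    return PosteriorSamples(chains)


# ---------------------------------------------------------------------------
# posterior predictive


def posterior_predictive(
    samples: PosteriorSamples,
    theta: kernel.MOGPHyperparams,
    panel: BiomarkerPanel,
    subject,
    biomarker,
    grid,
    include_noise: bool = False,
    seed: int = 0,
):
    """Pointwise median and 95% credible band of one biomarker's trajectory.

    For each retained draw the curve mu_ig + sum_a l_ga y_ia(t*) is evaluated
    on the requested grid; scores at times outside the common grid are drawn
    from the MOGP conditional MVN given that draw's augmented scores.  With
    ``include_noise`` the observation noise phi_g^2 is added.
    """
    i = _resolve(panel.subjects, subject, "subject")
    g = _resolve(panel.biomarkers, biomarker, "biomarker")
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    k, q = theta.k, panel.q
    pos = np.searchsorted(panel.grid, grid)
    pos = np.clip(pos, 0, q - 1)
    on = np.isclose(panel.grid[pos], grid)
    off_times = grid[~on]
    if off_times.size:
        s_star_t = _cov_between(theta, off_times, panel.grid)
        s_star_star = _cov_between(theta, off_times, off_times)
        K_inv = cho_solve(_chol(kernel.build_covariance(theta, panel.grid)),
                          np.eye(k * q))
        A_cond = s_star_t @ K_inv
        cov_cond = s_star_star - A_cond @ s_star_t.T
        chol_cond = _chol_dense(cov_cond + 1e-12 * np.eye(cov_cond.shape[0]))
        m_grid = kernel.mean_vector(theta, q)
        m_star = np.repeat(np.asarray(theta.means), off_times.size)
    curves = []
    for chain in samples.chains:
        for d in range(chain["L"].shape[0]):
            L_g = chain["L"][d][g]
            y = np.empty((k, grid.size))
            yaug = chain["Yaug"][d][i]
            y[:, on] = yaug[:, pos[on]]
            if off_times.size:
                dev = yaug.reshape(k * q) - m_grid
                draw = m_star + A_cond @ dev + chol_cond @ rng.standard_normal(
                    m_star.size
                )
                y[:, ~on] = draw.reshape(k, off_times.size)
            curve = chain["M"][d][i, g] + L_g @ y
            if include_noise:
                curve = curve + rng.standard_normal(grid.size) * np.sqrt(
                    chain["phi2"][d][g]
                )
            curves.append(curve)
    curves = np.asarray(curves)
    return {
        "grid": grid,
        "median": np.median(curves, axis=0),
        "lower": np.percentile(curves, 2.5, axis=0),
        "upper": np.percentile(curves, 97.5, axis=0),
    }


def _cov_between(theta, times1, times2):
    """Factor-major cross-covariance between scores at two sets of times."""
    t1 = np.asarray(times1, dtype=float)
    t2 = np.asarray(times2, dtype=float)
    D = t1[:, None] - t2[None, :]
    k = theta.k
    nuggets = theta.nuggets
    out = np.empty((k * t1.size, k * t2.size))
    for a in range(k):
        for b in range(k):
            if a == b:
                block = kernel.auto_covariance(theta.per_factor[a], float(nuggets[a]), D)
            else:
                block = kernel.cross_covariance(theta.per_factor[a], theta.per_factor[b], D)
            out[a * t1.size:(a + 1) * t1.size, b * t2.size:(b + 1) * t2.size] = block
    return out


def _resolve(labels, key, what):
    if key in labels:
        return labels.index(key)
    if isinstance(key, (int, np.integer)) and 0 <= key < len(labels):
        return int(key)
    raise KeyError(f"unknown {what}: {key!r}")
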