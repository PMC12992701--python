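"""Stochastic EM for the MOGP hyperparameters (Theta, C).

Each iteration alternates an S-step -- a Gibbs chain at the current
hyperparameters from which ONE post-burn-in draw of the augmented factor
scores is taken uniformly at random -- with an M-step that maximizes the
roughness-penalized common-grid MVN log-likelihood

    sum_i ln MVN(vec(Y_i,aug^T) | C_aug, Sigma_Yaug(Theta, t))
        - lambda * sum_a (B_a0 + B_a1)

by L-BFGS-B in an unconstrained parameterization.  The iterates form a
homogeneous Markov chain; the final estimate is the average of the last m
iterates, taken in the transformed parameter space.

Identifiability: each factor's stationary variance is held at 1 by
construction.  Per factor the parameters are (ln B_a0, ln B_a1, gamma_a),
where gamma_a splits the non-nugget variance between the shared and specific
components -- the shared fraction is gamma_a^2 / (1 + gamma_a^2) and
sign(gamma_a) carries the sign of the shared amplitude v_a0 (hence of the
cross-correlations).  A single logit-parameterized nugget share psi^2 is
shared across factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.special import expit, logit

from . import align as _align
from . import kernel
from .gibbs import (
    FactorBlockCache,
    _PanelCache,
    _chol,
    gibbs_sweep,
    init_state_data_driven,
)
from .model import BiomarkerPanel, PriorConfig

__all__ = [
    "StemConfig",
    "StemTrace",
    "penalized_mvn_objective",
    "m_step",
    "stem_fit",
    "estimate_from_trace",
    "initial_theta",
    "pack_theta",
    "unpack_theta",
]

_LOG_B_BOUND = 12.0


@dataclass(frozen=True)
class StemConfig:
    """Run lengths and optimizer settings for the stochastic EM loop.

    ``n_iters`` stochastic-EM iterations; the final estimate averages the last
    ``m`` of them.  Each S-step runs a Gibbs chain of ``s_chain_len`` sweeps
    (warm-started from the previous iteration) and draws one sample uniformly
    from the iterations after the ``s_burn_frac`` burn-in.
    """

    n_iters: int = 200
    m: int = 50
    s_chain_len: int = 500
    s_burn_frac: float = 0.2
    max_opt_iter: int = 60

    def __post_init__(self) -> None:
        if self.m > self.n_iters:
            raise ValueError("averaging window m must not exceed n_iters")
        if self.s_chain_len < 1:
            raise ValueError("s_chain_len must be >= 1")


@dataclass
class StemTrace:
    """Per-iteration record of the transformed parameters and objective."""

    vecs: list = field(default_factory=list)       # packed (3k+1)-vectors
    means: list = field(default_factory=list)      # c_a vectors
    objectives: list = field(default_factory=list)
    flags: list = field(default_factory=list)      # True where the M-step failed

    def __len__(self) -> int:
        return len(self.vecs)

    def theta(self, l: int) -> kernel.MOGPHyperparams:
        k = len(self.means[l])
        return unpack_theta(np.asarray(self.vecs[l]), k, self.means[l])

    def to_dataframe(self) -> pd.DataFrame:
        k = len(self.means[0]) if self.means else 0
        cols = {}
        for a in range(k):
            cols[f"logB{a}0"] = [v[3 * a] for v in self.vecs]
            cols[f"logB{a}1"] = [v[3 * a + 1] for v in self.vecs]
            cols[f"gamma{a}"] = [v[3 * a + 2] for v in self.vecs]
            cols[f"c{a}"] = [c[a] for c in self.means]
        cols["zeta"] = [v[-1] for v in self.vecs]
        cols["objective"] = self.objectives
        cols["m_step_failed"] = self.flags
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# unit-variance parameterization


def unpack_theta(vec: np.ndarray, k: int, means=None) -> kernel.MOGPHyperparams:
    """Transformed vector -> hyperparameters with unit stationary variances."""
    vec = np.asarray(vec, dtype=float)
    zeta = vec[-1]
    psi2 = float(expit(zeta))
    V = 1.0 - psi2
    pf = []
    for a in range(k):
        lb0, lb1, gamma = vec[3 * a: 3 * a + 3]
        B0, B1 = math.exp(lb0), math.exp(lb1)
        w = gamma**2 / (1.0 + gamma**2)
        v0 = math.copysign(math.sqrt(w * V) * (B0 / math.pi) ** 0.25, gamma)
        v1 = math.sqrt((1.0 - w) * V) * (B1 / math.pi) ** 0.25
        pf.append(kernel.FactorKernelParams(v0=v0, v1=v1, B0=B0, B1=B1))
    return kernel.MOGPHyperparams(tuple(pf), psi2, means)


def pack_theta(theta: kernel.MOGPHyperparams) -> np.ndarray:
    """Hyperparameters -> transformed vector (requires unit variances)."""
    nuggets = theta.nuggets
    psi2 = float(np.mean(nuggets))
    psi2 = min(max(psi2, 1e-12), 1 - 1e-12)
    V = 1.0 - psi2
    out = np.empty(3 * theta.k + 1)
    for a, p in enumerate(theta.per_factor):
        var = kernel.stationary_variance(p, float(nuggets[a]))
        if abs(var - 1.0) > 1e-6:
            raise ValueError("pack_theta requires unit-variance hyperparameters")
        w = p.v0**2 * math.sqrt(math.pi / p.B0) / V
        w = min(max(w, 1e-12), 1 - 1e-12)
        gamma = math.copysign(math.sqrt(w / (1.0 - w)), p.v0 if p.v0 != 0 else 1.0)
        out[3 * a: 3 * a + 3] = (math.log(p.B0), math.log(p.B1), gamma)
    out[-1] = logit(psi2)
    return out


def initial_theta(k: int, grid) -> kernel.MOGPHyperparams:
    """Scale-aware neutral start: shared-component correlation halves at a
    quarter of the observed time span; equal shared/specific/nugget variance
    shares; zero means."""
    grid = np.asarray(grid, dtype=float)
    span = float(grid.max() - grid.min()) if grid.size > 1 else 1.0
    span = span if span > 0 else 1.0
    B = 64.0 * math.log(2.0) / span**2
    vec = np.empty(3 * k + 1)
    for a in range(k):
        vec[3 * a: 3 * a + 3] = (math.log(B), math.log(B), 1.0)
    vec[-1] = logit(1.0 / 3.0)
    return unpack_theta(vec, k, np.zeros(k))


# ---------------------------------------------------------------------------
# objective and M-step


def penalized_mvn_objective(y_aug: np.ndarray, theta: kernel.MOGPHyperparams,
                            grid, lam: float) -> float:
    """Common-grid MVN log-likelihood of the augmented scores minus the
    roughness penalty lambda * sum_a (B_a0 + B_a1)."""
    grid = np.asarray(grid, dtype=float)
    n = y_aug.shape[0]
    k, q = theta.k, grid.size
    cov = kernel.build_covariance(theta, grid)
    c = _chol(cov)
    mean = kernel.mean_vector(theta, q)
    dev = y_aug.reshape(n, k * q) - mean
    logdet = 2.0 * np.log(np.diag(c[0])).sum()
    quad = float(np.square(solve_triangular(c[0], dev.T, lower=True)).sum())
    ll = -0.5 * (n * (k * q * math.log(2 * math.pi) + logdet) + quad)
    penalty = lam * sum(p.B0 + p.B1 for p in theta.per_factor)
    return ll - penalty


def _profile_means(y_aug: np.ndarray, chol, k: int, q: int) -> np.ndarray:
    """GLS closed form for the constant factor means given the covariance."""
    n = y_aug.shape[0]
    ybar = y_aug.reshape(n, k * q).mean(axis=0)
    D = np.kron(np.eye(k), np.ones((q, 1)))
    SiD = cho_solve(chol, D)
    return np.linalg.solve(D.T @ SiD, SiD.T @ ybar)


def m_step(
    y_aug: np.ndarray,
    grid,
    lam: float,
    init_theta: kernel.MOGPHyperparams,
    max_opt_iter: int = 60,
) -> tuple[kernel.MOGPHyperparams, bool]:
    """Maximize the penalized objective over (Theta, C) from a warm start.

    The constant means C are profiled out in closed form at every objective
    evaluation.  Returns the best evaluated point; the flag is True when the
    optimizer failed to improve on the initial value (the initial point is
    then returned, so the update never degrades the objective).
    """
    grid = np.asarray(grid, dtype=float)
    k, q = init_theta.k, grid.size
    n = y_aug.shape[0]
    x0 = pack_theta(init_theta)
    best = {"obj": -np.inf, "vec": None, "c": None}

    def neg(vecx):
        theta = unpack_theta(vecx, k)
        try:
            cov = kernel.build_covariance(theta, grid)
            c_fac = _chol(cov)
            cvec = _profile_means(y_aug, c_fac, k, q)
            mean = np.repeat(cvec, q)
            dev = y_aug.reshape(n, k * q) - mean
            logdet = 2.0 * np.log(np.diag(c_fac[0])).sum()
            quad = float(np.square(solve_triangular(c_fac[0], dev.T, lower=True)).sum())
            ll = -0.5 * (n * (k * q * math.log(2 * math.pi) + logdet) + quad)
            obj = ll - lam * sum(p.B0 + p.B1 for p in theta.per_factor)
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e300
        if not np.isfinite(obj):
            return 1e300
        if obj > best["obj"]:
            best.update(obj=obj, vec=np.array(vecx), c=np.array(cvec))
        return -obj

    bounds = []
    for _ in range(k):
        bounds += [(-_LOG_B_BOUND, _LOG_B_BOUND)] * 2 + [(-30.0, 30.0)]
    bounds.append((-12.0, 6.0))
    neg(x0)
    init_obj = best["obj"]
    res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": max_opt_iter})
    # the best point seen is at least the warm start, so no degradation
    failed = (not res.success) and not (best["obj"] > init_obj)
    theta_new = unpack_theta(best["vec"], k, best["c"])
    return theta_new, bool(failed)


def estimate_from_trace(trace: StemTrace, m: int) -> kernel.MOGPHyperparams:
    """Trailing-window average of the last m iterates in transformed space."""
    if m > len(trace):
        raise ValueError(f"m={m} exceeds trace length {len(trace)}")
    if m < 1:
        raise ValueError("m must be >= 1")
    vec = np.mean([np.asarray(v) for v in trace.vecs[-m:]], axis=0)
    means = np.mean([np.asarray(c) for c in trace.means[-m:]], axis=0)
    k = means.size
    return unpack_theta(vec, k, means)


# ---------------------------------------------------------------------------
# driver


def stem_fit(
    panel: BiomarkerPanel,
    k: int,
    lam: float,
    stem_config: StemConfig | None = None,
    priors: PriorConfig | None = None,
    seed: int = 0,
) -> tuple[kernel.MOGPHyperparams, StemTrace]:
    """Estimate (Theta, C) by stochastic EM; returns the trailing-window
    average estimate (means carried in ``theta.means``) and the full trace.

    The S-step Gibbs chain is warm-started across iterations; all randomness
    derives deterministically from ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cfg = stem_config or StemConfig()
    priors = priors or PriorConfig.default(panel)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    theta = initial_theta(k, panel.grid)
    pcache = _PanelCache(panel)
    state = init_state_data_driven(panel, k, priors, theta, rng)
    # moment-match the starting hyperparameters to the initialization scores
    # (an M-step on them); a start far from the data moments would cost many
    # early iterations, as the factor prior feeds back into the S-step draws
    theta0, failed0 = m_step(np.array(state.Yaug), panel.grid, lam, theta,
                             max_opt_iter=cfg.max_opt_iter)
    if not failed0:
        theta = theta0
    trace = StemTrace()
    n_burn = int(cfg.s_burn_frac * cfg.s_chain_len)
    n_keep = cfg.s_chain_len - n_burn
    L_ref = None
    for _ in range(cfg.n_iters):
        fcache = FactorBlockCache(theta, panel)
        pick = n_burn + int(rng.integers(n_keep))
        y_draw = L_pick = None
        for it in range(cfg.s_chain_len):
            gibbs_sweep(state, panel, priors, fcache, pcache, rng)
            if it == pick:
                y_draw = np.array(state.Yaug)
                L_pick = state.L
        # keep the whole trajectory in one labeling mode: re-align the draw,
        # the chain state and the warm start to a running loading reference
        if L_ref is None:
            L_ref = L_pick
        sp_draw = _align.best_signed_permutation(L_pick, L_ref)
        signs = np.asarray(sp_draw.signs, dtype=float)
        y_draw = y_draw[:, list(sp_draw.perm), :] * signs[None, :, None]
        theta_warm = _align.apply_to_theta(sp_draw, theta)
        sp_state = _align.best_signed_permutation(state.L, L_ref)
        _align.apply_to_state(sp_state, state)
        L_ref = state.L
        theta_new, failed = m_step(y_draw, panel.grid, lam, theta_warm,
                                   max_opt_iter=cfg.max_opt_iter)
        theta = theta_warm
        if not failed:
            theta = theta_new
        trace.vecs.append(pack_theta(theta))
        trace.means.append(np.asarray(theta.means, dtype=float))
        trace.objectives.append(
            penalized_mvn_objective(y_draw, theta, panel.grid, lam)
        )
        trace.flags.append(failed)
    theta_hat = estimate_from_trace(trace, cfg.m)
    return theta_hat, trace
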