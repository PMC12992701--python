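"""Synthetic longitudinal biomarker panels with known ground truth.

Two sampling designs are provided:

* a regular benchmark design mimicking longitudinal gene-expression panels:
  k=4 correlated factors, p=100 biomarkers, q_i=8 common visit times, each
  factor regulating ~10% of biomarkers with loadings drawn from N(4, 1),
  grand means spaced over [4, 16], sigma_g = phi_g = 0.5;
* an irregular design emulating a COVID-19 metabolite study: n=101 subjects,
  p=35 biomarkers, 2-5 visits each (about half with only 2) drawn without
  replacement from 50 integer days.

Factor scores can be drawn either i.i.d. across time from a fixed k x k
correlation matrix, or from a convolution-process MOGP with chosen
hyperparameters (temporally smooth trajectories).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import kernel
from .model import BiomarkerPanel

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "default_benchmark_config",
    "covid_like_config",
    "generate",
    "theta_from_correlation",
    "default_correlation",
]


def default_correlation(k: int) -> np.ndarray:
    """A positive-definite unit-diagonal correlation matrix with non-zero
    cross-correlations between all factor pairs (defaults used at k=4)."""
    if k == 4:
        rho = np.eye(4)
        vals = {(0, 1): 0.6, (0, 2): 0.3, (0, 3): 0.1,
                (1, 2): 0.3, (1, 3): 0.1, (2, 3): 0.1}
        for (a, b), v in vals.items():
            rho[a, b] = rho[b, a] = v
        return rho
    rho = np.full((k, k), 0.3)
    np.fill_diagonal(rho, 1.0)
    return rho


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults are the regular benchmark design."""

    n: int = 100
    p: int = 100
    k: int = 4
    design: str = "regular"            # "regular" | "irregular"
    q: int = 8                          # visits per subject (regular design)
    n_days: int = 50                    # day grid 0..n_days-1 (irregular design)
    visit_range: tuple[int, int] = (2, 5)
    two_visit_frac: float = 0.5
    y_mode: str = "iid"                 # "iid" | "mogp"
    correlation: np.ndarray | None = None   # k x k Sigma_Y (iid mode)
    theta: kernel.MOGPHyperparams | None = None  # CP hyperparameters (mogp mode)
    regulation_prob: float = 0.1
    loading_mean: float = 4.0
    loading_sd: float = 1.0
    mu_range: tuple[float, float] = (4.0, 16.0)
    sigma_g: float = 0.5
    phi_g: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.regulation_prob <= 1.0:
            raise ValueError("regulation_prob must be in [0, 1]")
        if self.sigma_g < 0 or self.phi_g < 0:
            raise ValueError("noise scales must be non-negative")
        if self.design not in ("regular", "irregular"):
            raise ValueError("design must be 'regular' or 'irregular'")
        if self.y_mode not in ("iid", "mogp"):
            raise ValueError("y_mode must be 'iid' or 'mogp'")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            if c.shape != (self.k, self.k) or not np.allclose(np.diag(c), 1.0):
                raise ValueError("correlation must be k x k with unit diagonal")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ValueError("correlation matrix must be positive semi-definite")
            object.__setattr__(self, "correlation", c)


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating quantities stored alongside a simulated panel."""

    L: np.ndarray            # p x k loadings
    Z: np.ndarray
    Y: list                  # per-subject k x q_i score matrices
    M: np.ndarray            # n x p subject-biomarker means
    correlation: np.ndarray  # k x k factor cross-correlation matrix
    pi: np.ndarray


@dataclass(frozen=True)
class SyntheticDataset:
    panel: BiomarkerPanel
    truth: SyntheticTruth
    config: SimConfig
    seed: int


def default_benchmark_config(n: int) -> SimConfig:
    """Regular-sampling benchmark: k=4, p=100, q_i=8, 10% regulation,
    loadings N(4,1), grand means in [4,16], sigma_g = phi_g = 0.5, correlated
    factors (i.i.d. across time with the default correlation matrix)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return SimConfig(n=n, correlation=default_correlation(4))


def covid_like_config() -> SimConfig:
    """Irregular-sampling design shaped like the COVID-19 metabolite study:
    n=101 subjects, p=35 biomarkers, 2-5 integer-day visits in 0..49 with
    roughly half the subjects observed only twice."""
    return SimConfig(
        n=101, p=35, k=2, design="irregular", n_days=50,
        correlation=default_correlation(2),
    )


def theta_from_correlation(
    corr: np.ndarray, B0: float = 0.7, B1: float = 0.7, psi2: float = 0.1
) -> kernel.MOGPHyperparams:
    """CP hyperparameters with unit variances whose zero-lag correlation
    matrix equals ``corr``.

    A single shared base process induces rank-one cross-correlation
    rho_ab = u_a u_b, so ``corr`` must satisfy corr[a, b] = u_a * u_b off the
    diagonal for some vector u with u_a^2 <= 1 - psi2 (always possible for
    k = 2; raises otherwise).
    """
    corr = np.asarray(corr, dtype=float)
    k = corr.shape[0]
    if k == 1:
        u = np.array([math.sqrt(0.5 * (1 - psi2))])
    elif k == 2:
        r = corr[0, 1]
        u0 = math.sqrt(abs(r)) if r != 0 else math.sqrt(0.5 * (1 - psi2))
        u = np.array([u0, math.copysign(u0, r) if r != 0 else u0])
    else:
        # rank-one factorization check: corr_ab = u_a u_b for a != b
        with np.errstate(invalid="ignore"):
            u = np.sqrt(np.abs(corr[0, 1] * corr[0, 2] / corr[1, 2])) if k >= 3 else None
        u_vec = np.empty(k)
        u_vec[0] = u
        for a in range(1, k):
            u_vec[a] = corr[0, a] / u_vec[0]
        rebuilt = np.outer(u_vec, u_vec)
        iu = np.triu_indices(k, 1)
        if not np.allclose(rebuilt[iu], corr[iu], atol=1e-8):
            raise ValueError(
                "a single shared base process induces rank-one cross-correlations; "
                "the requested matrix is not rank-one"
            )
        u = u_vec
    if np.any(u**2 > 1 - psi2 + 1e-12):
        raise ValueError("requested correlations too large for the given nugget share")
    pf = []
    for a in range(k):
        shared_var = u[a] ** 2
        spec_var = 1.0 - psi2 - shared_var
        v0 = math.copysign(math.sqrt(shared_var) * (B0 / math.pi) ** 0.25, u[a])
        v1 = math.sqrt(max(spec_var, 0.0)) * (B1 / math.pi) ** 0.25
        pf.append(kernel.FactorKernelParams(v0=v0, v1=v1, B0=B0, B1=B1))
    return kernel.MOGPHyperparams(tuple(pf), psi2, np.zeros(k))


def _draw_visit_times(config: SimConfig, rng: np.random.Generator):
    """Per-subject sorted visit-day index arrays for the irregular design."""
    lo, hi = config.visit_range
    counts = np.where(
        rng.random(config.n) < config.two_visit_frac,
        lo,
        rng.integers(lo + 1, hi + 1, size=config.n),
    )
    return [np.sort(rng.choice(config.n_days, size=c, replace=False)) for c in counts]


def generate(config: SimConfig, seed: int = 0) -> SyntheticDataset:
    """Draw a complete synthetic dataset; bit-reproducible from (config, seed)."""
    rng = np.random.default_rng(seed)
    n, p, k = config.n, config.p, config.k

    if config.design == "regular":
        day_sets = [np.arange(config.q)] * n
        grid = np.arange(config.q, dtype=float)
    else:
        day_sets = _draw_visit_times(config, rng)
        used = sorted(set(int(d) for days in day_sets for d in days))
        remap = {d: j for j, d in enumerate(used)}
        grid = np.asarray(used, dtype=float)
        day_sets = [np.asarray(days) for days in day_sets]

    # sparsity pattern and loadings
    c0 = config.regulation_prob * p
    d0 = (1 - config.regulation_prob) * p
    pi = rng.beta(c0, d0, size=k)
    Z = (rng.random((p, k)) < pi[None, :]).astype(int)
    A = config.loading_mean + config.loading_sd * rng.standard_normal((p, k))
    L = A * Z

    # factor scores
    if config.y_mode == "iid":
        corr = (config.correlation if config.correlation is not None
                else default_correlation(k))
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
        Y = [
            chol @ rng.standard_normal((k, len(days)))
            for days in day_sets
        ]
    else:
        theta = config.theta
        if theta is None:
            theta = theta_from_correlation(
                config.correlation if config.correlation is not None
                else default_correlation(k)
            )
        corr = kernel.cross_correlation_matrix(theta)
        Y = []
        for days in day_sets:
            times = np.asarray(days, dtype=float)
            cov = kernel.build_covariance(theta, times)
            chol = np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))
            vec = chol @ rng.standard_normal(cov.shape[0])
            Y.append(vec.reshape(k, times.size))

    # means and observations
    mu_g = np.linspace(config.mu_range[0], config.mu_range[1], p)
    M = mu_g[None, :] + config.sigma_g * rng.standard_normal((n, p))
    X, obs_idx = [], []
    for i, days in enumerate(day_sets):
        qi = len(days)
        mean = M[i][:, None] + L @ Y[i]
        X.append(mean + config.phi_g * rng.standard_normal((p, qi)))
        if config.design == "regular":
            obs_idx.append(np.arange(qi))
        else:
            obs_idx.append(np.array([remap[int(d)] for d in days]))

    panel = BiomarkerPanel(
        subjects=[f"S{i:03d}" for i in range(n)],
        biomarkers=[f"B{g:03d}" for g in range(p)],
        grid=grid,
        obs_idx=obs_idx,
        X=X,
    )
    truth = SyntheticTruth(L=L, Z=Z, Y=Y, M=M, correlation=corr, pi=pi)
    return SyntheticDataset(panel=panel, truth=truth, config=config, seed=seed)
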