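"""Model state, priors and deterministic model equations.

Observation model (long-format biomarker panel):

    x_ijg = mu_ig + sum_a l_ga * y_ija + e_ijg,   e_ijg ~ N(0, phi_g^2)

with spike-and-slab loadings l_ga = Z_ga * A_ga (Z ~ Bernoulli(pi_a),
pi_a ~ Beta(c0, d0), A ~ N(0, rho_a^2), rho_a^2 ~ InvGamma(c1, d1)),
subject-biomarker means mu_ig ~ N(mu_g, sigma_g^2) and conjugate
Inverse-Gamma priors on all variances.  Factor scores carry the MOGP prior of
:mod:`mogpfa.kernel` on the common augmented grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, solve_triangular

from . import kernel

__all__ = [
    "PriorConfig",
    "BiomarkerPanel",
    "LatentState",
    "model_mean",
    "complete_data_loglik",
]


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of all conjugate priors plus the fixed grand means mu_g.

    c0, d0 control expected sparsity: E[pi_a] = c0 / (c0 + d0).  The defaults
    from :meth:`default` use c0 = 0.1 p, d0 = 0.9 p (10% of biomarkers per
    factor) and weakly informative unit Inverse-Gamma parameters elsewhere.
    """

    c0: float
    d0: float
    c1: float = 1.0
    d1: float = 1.0
    c2: float = 1.0
    d2: float = 1.0
    c3: float = 1.0
    d3: float = 1.0
    mu_g: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        for name in ("c0", "d0", "c1", "d1", "c2", "d2", "c3", "d3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior hyperparameter {name} must be positive")
        object.__setattr__(self, "mu_g", np.asarray(self.mu_g, dtype=float))

    @classmethod
    def default(cls, panel: "BiomarkerPanel", expected_sparsity: float = 0.1) -> "PriorConfig":
        """Defaults with mu_g fixed to each biomarker's empirical mean."""
        p = panel.p
        return cls(
            c0=expected_sparsity * p,
            d0=(1.0 - expected_sparsity) * p,
            mu_g=panel.biomarker_means(),
        )


class BiomarkerPanel:
    """Long-format longitudinal biomarker measurements on irregular times.

    Internally stores, per subject, a dense p x q_i matrix of values together
    with the indices of that subject's visit times in the global sorted unique
    grid ``t`` (the union of all subjects' times).  Every visit must record all
    p biomarkers.
    """

    def __init__(self, subjects, biomarkers, grid, obs_idx, X):
        self.subjects = list(subjects)
        self.biomarkers = list(biomarkers)
        self.grid = np.asarray(grid, dtype=float)
        self.obs_idx = [np.asarray(ix, dtype=int) for ix in obs_idx]
        self.X = [np.asarray(x, dtype=float) for x in X]
        self._validate()

    def _validate(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid times must be strictly increasing")
        if len(self.obs_idx) != self.n or len(self.X) != self.n:
            raise ValueError("per-subject structures must have length n")
        for i, (ix, x) in enumerate(zip(self.obs_idx, self.X)):
            if ix.size == 0:
                raise ValueError(f"subject {self.subjects[i]} has no observations")
            if np.any(np.diff(ix) <= 0):
                raise ValueError("per-subject time indices must be strictly increasing")
            if x.shape != (self.p, ix.size):
                raise ValueError(
                    f"subject {self.subjects[i]}: value matrix shape {x.shape} "
                    f"!= ({self.p}, {ix.size})"
                )

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def p(self) -> int:
        return len(self.biomarkers)

    @property
    def q(self) -> int:
        return self.grid.size

    @property
    def q_i(self) -> np.ndarray:
        return np.array([ix.size for ix in self.obs_idx])

    def times(self, i: int) -> np.ndarray:
        """Observation times of subject i."""
        return self.grid[self.obs_idx[i]]

    def biomarker_means(self) -> np.ndarray:
        """Empirical mean of each biomarker pooled over all subject-times."""
        total = sum(x.sum(axis=1) for x in self.X)
        count = int(self.q_i.sum())
        return total / count

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "BiomarkerPanel":
        """Build a panel from a long table (subject, time, biomarker, value)."""
        required = {"subject", "time", "biomarker", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        df = df.copy()
        df["time"] = pd.to_numeric(df["time"], errors="raise")
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        dup = df.duplicated(["subject", "time", "biomarker"], keep=False)
        if dup.any():
            first = df.loc[dup, ["subject", "time", "biomarker"]].iloc[0].tolist()
            raise ValueError(f"duplicate (subject, time, biomarker) rows, e.g. {first}")
        subjects = sorted(df["subject"].unique().tolist())
        biomarkers = sorted(df["biomarker"].unique().tolist())
        grid = np.sort(df["time"].unique())
        gpos = {t: j for j, t in enumerate(grid)}
        bpos = {g: r for r, g in enumerate(biomarkers)}
        obs_idx, X = [], []
        for s in subjects:
            sub = df[df["subject"] == s]
            tset = np.sort(sub["time"].unique())
            ix = np.array([gpos[t] for t in tset])
            x = np.full((len(biomarkers), ix.size), np.nan)
            tcol = {t: j for j, t in enumerate(tset)}
            x[[bpos[g] for g in sub["biomarker"]],
              [tcol[t] for t in sub["time"]]] = sub["value"].to_numpy()
            if np.isnan(x).any():
                raise ValueError(
                    f"subject {s}: every visit must record all {len(biomarkers)} biomarkers"
                )
            obs_idx.append(ix)
            X.append(x)
        return cls(subjects, biomarkers, grid, obs_idx, X)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.subjects):
            t = self.times(i)
            for r, g in enumerate(self.biomarkers):
                for j in range(t.size):
                    rows.append((s, t[j], g, self.X[i][r, j]))
        return pd.DataFrame(rows, columns=["subject", "time", "biomarker", "value"])

    def subset(self, indices) -> "BiomarkerPanel":
        """Panel restricted to a subset of subjects (grid recomputed)."""
        indices = list(indices)
        used = sorted(set(np.concatenate([self.obs_idx[i] for i in indices]).tolist()))
        remap = {old: new for new, old in enumerate(used)}
        return BiomarkerPanel(
            [self.subjects[i] for i in indices],
            self.biomarkers,
            self.grid[used],
            [np.array([remap[j] for j in self.obs_idx[i]]) for i in indices],
            [self.X[i] for i in indices],
        )


@dataclass
class LatentState:
    """All unknowns other than the MOGP hyperparameters (Omega_aug)."""

    A: np.ndarray        # p x k slab coefficients
    Z: np.ndarray        # p x k binary inclusion indicators
    M: np.ndarray        # n x p subject-biomarker means
    Yaug: np.ndarray     # n x k x q factor scores on the common grid
    pi: np.ndarray       # k
    rho2: np.ndarray     # k
    sigma2: np.ndarray   # p
    phi2: np.ndarray     # p

    @property
    def L(self) -> np.ndarray:
        """Sparse loading matrix L = A o Z."""
        return self.A * self.Z

    def copy(self) -> "LatentState":
        return LatentState(*(np.array(getattr(self, f)) for f in
                             ("A", "Z", "M", "Yaug", "pi", "rho2", "sigma2", "phi2")))

    def validate(self, panel: BiomarkerPanel, k: int) -> None:
        p, n, q = panel.p, panel.n, panel.q
        if self.A.shape != (p, k) or self.Z.shape != (p, k):
            raise ValueError("A/Z must be p x k")
        if self.M.shape != (n, p):
            raise ValueError("M must be n x p")
        if self.Yaug.shape != (n, k, q):
            raise ValueError("Yaug must be n x k x q")
        if not np.isin(self.Z, (0, 1)).all():
            raise ValueError("Z entries must be 0/1")
        if np.any((self.pi <= 0) | (self.pi >= 1)):
            raise ValueError("pi must lie in (0, 1)")
        for name in ("rho2", "sigma2", "phi2"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")


def model_mean(state: LatentState, panel: BiomarkerPanel, i: int) -> np.ndarray:
    """Predicted mean matrix M_i + L Y_i (p x q_i) for one subject."""
    Yi = state.Yaug[i][:, panel.obs_idx[i]]
    return state.M[i][:, None] + state.L @ Yi


def complete_data_loglik(
    panel: BiomarkerPanel,
    state: LatentState,
    theta: kernel.MOGPHyperparams,
    priors: PriorConfig,
) -> float:
    """Complete-data log density ln f(X, Omega_aug | Theta, C).

    Sum of the Gaussian observation terms, the MVN MOGP prior on each
    subject's augmented factor scores, and the log prior densities of all
    remaining unknowns.
    """
    ll = observation_loglik(panel, state)
    # MOGP prior on the common grid, one Cholesky shared across subjects
    cov = kernel.build_covariance(theta, panel.grid)
    mean = kernel.mean_vector(theta, panel.q)
    c, low = _chol_with_jitter(cov)
    kq = cov.shape[0]
    logdet = 2.0 * np.log(np.diag(c)).sum()
    dev = state.Yaug.reshape(panel.n, kq) - mean
    quad = np.square(solve_triangular(c, dev.T, lower=low)).sum()
    ll += -0.5 * (panel.n * (kq * np.log(2 * np.pi) + logdet) + quad)
    # priors
    mu_g = priors.mu_g if priors.mu_g.size else np.zeros(panel.p)
    ll += stats.norm.logpdf(state.M, mu_g[None, :], np.sqrt(state.sigma2)[None, :]).sum()
    ll += stats.norm.logpdf(state.A, 0.0, np.sqrt(state.rho2)[None, :]).sum()
    ll += float(np.sum(state.Z * np.log(state.pi) + (1 - state.Z) * np.log1p(-state.pi)))
    ll += stats.beta.logpdf(state.pi, priors.c0, priors.d0).sum()
    ll += stats.invgamma.logpdf(state.rho2, priors.c1, scale=priors.d1).sum()
    ll += stats.invgamma.logpdf(state.sigma2, priors.c2, scale=priors.d2).sum()
    ll += stats.invgamma.logpdf(state.phi2, priors.c3, scale=priors.d3).sum()
    if not np.isfinite(ll):
        raise ValueError("complete-data log-likelihood is not finite")
    return float(ll)


def observation_loglik(panel: BiomarkerPanel, state: LatentState) -> float:
    """Gaussian observation terms sum_ijg ln N(x_ijg | mu_ig + (L y)_ijg, phi_g^2)."""
    ll = 0.0
    sd = np.sqrt(state.phi2)
    for i in range(panel.n):
        resid = panel.X[i] - model_mean(state, panel, i)
        qi = resid.shape[1]
        ll += float(
            -0.5 * np.sum(resid**2 / state.phi2[:, None])
            - qi * np.sum(np.log(sd))
            - 0.5 * panel.p * qi * np.log(2 * np.pi)
        )
    return ll


def _chol_with_jitter(cov: np.ndarray):
    """Cholesky with one retry after adding jitter 1e-8 * mean(diag)."""
    try:
        return cho_factor(cov, lower=True)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * float(np.mean(np.diag(cov)))
        return cho_factor(cov + jitter * np.eye(cov.shape[0]), lower=True)
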