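"""Convolution-process multi-output Gaussian process covariances.

Each latent factor trajectory ``y_a(t)`` is built by convolving Gaussian
smoothing kernels ``h(t) = v * exp(-B t^2 / 2)`` against white-noise base
processes: one base process shared by all factors (inducing cross-correlation)
and one specific to each factor, plus an i.i.d. nugget ``psi^2``.

For two kernels with parameters ``(v_a, B_a)`` and ``(v_b, B_b)`` driven by the
same unit white noise, the induced covariance at lag ``dt`` is the Gaussian
convolution integral

    C(dt) = v_a v_b * sqrt(2*pi / (B_a + B_b))
            * exp(-0.5 * B_a B_b / (B_a + B_b) * dt^2),

which for ``a == b`` reduces to ``v^2 sqrt(pi/B) exp(-B dt^2 / 4)``.  At zero
lag the shared component gives the constant cross-covariance
``v_a0 v_b0 sqrt(2*pi) / sqrt(B_a0 + B_b0)``.  All closed forms here are
validated against adaptive quadrature of the defining convolution integral in
the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FactorKernelParams",
    "MOGPHyperparams",
    "auto_covariance",
    "cross_covariance",
    "build_covariance",
    "cross_correlation",
    "normalize_unit_variance",
    "stationary_variance",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class FactorKernelParams:
    """Kernel parameters of one factor: shared (v0, B0) and specific (v1, B1).

    ``v0``/``v1`` are amplitudes of the kernels convolved against the shared
    and factor-specific white-noise base processes; ``B0``/``B1`` (> 0) are
    decay rates controlling smoothness (larger B = rougher trajectories).
    """

    v0: float
    v1: float
    B0: float
    B1: float

    def __post_init__(self) -> None:
        if not (self.B0 > 0 and self.B1 > 0):
            raise ValueError(f"decay rates must be positive, got B0={self.B0}, B1={self.B1}")
        if not all(map(math.isfinite, (self.v0, self.v1, self.B0, self.B1))):
            raise ValueError("kernel parameters must be finite")


@dataclass(frozen=True)
class MOGPHyperparams:
    """Full MOGP hyperparameter set Theta = {v, B}, nugget psi^2, means c_a.

    ``nugget`` may be a single shared value (the model's prior form) or a
    per-factor sequence; normalization to unit stationary variance produces
    per-factor nuggets.
    """

    per_factor: tuple[FactorKernelParams, ...]
    nugget: float | tuple[float, ...] = 0.0
    means: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_factor", tuple(self.per_factor))
        if isinstance(self.nugget, (list, tuple, np.ndarray)):
            ng = tuple(float(x) for x in self.nugget)
            if len(ng) != self.k:
                raise ValueError("per-factor nugget length must equal k")
        else:
            ng = float(self.nugget)
        object.__setattr__(self, "nugget", ng)
        if np.any(np.asarray(self.nuggets) < 0):
            raise ValueError("nugget must be non-negative")
        if self.means is None:
            object.__setattr__(self, "means", tuple(0.0 for _ in self.per_factor))
        else:
            object.__setattr__(self, "means", tuple(float(c) for c in self.means))
        if len(self.means) != self.k:
            raise ValueError("means length must equal k")

    @property
    def k(self) -> int:
        return len(self.per_factor)

    @property
    def nuggets(self) -> np.ndarray:
        """Per-factor nugget variances as an array of length k."""
        if isinstance(self.nugget, tuple):
            return np.asarray(self.nugget)
        return np.full(self.k, self.nugget)


def _conv_component(va, Ba, vb, Bb, dt):
    """Covariance of two kernel-convolved processes sharing one base process."""
    s = Ba + Bb
    dt = np.asarray(dt, dtype=float)
    return va * vb * _SQRT_2PI / math.sqrt(s) * np.exp(-0.5 * Ba * Bb / s * dt**2)


def auto_covariance(params: FactorKernelParams, nugget: float, dt):
    """Auto-covariance C_aa(dt) of one factor: shared + specific + nugget.

    Stationary: depends on dt only through |dt|.  The nugget contributes only
    at exactly zero lag.
    """
    if nugget < 0:
        raise ValueError("nugget must be non-negative")
    dt = np.asarray(dt, dtype=float)
    val = _conv_component(params.v0, params.B0, params.v0, params.B0, dt)
    val = val + _conv_component(params.v1, params.B1, params.v1, params.B1, dt)
    return val + np.where(dt == 0.0, nugget, 0.0)


def cross_covariance(params_a: FactorKernelParams, params_b: FactorKernelParams, dt):
    """Cross-covariance between two factors, induced by the shared base process only."""
    return _conv_component(params_a.v0, params_a.B0, params_b.v0, params_b.B0, dt)


def stationary_variance(params: FactorKernelParams, nugget: float) -> float:
    """C_aa(0): total stationary variance of one factor including the nugget."""
    return float(auto_covariance(params, nugget, 0.0))


def build_covariance(theta: MOGPHyperparams, times, k: int | None = None) -> np.ndarray:
    """Assemble the kq x kq covariance of vec(Y_i^T) on a given time grid.

    Stacking is factor-major: entries ``a*q + j`` hold factor ``a`` at time
    ``times[j]``, matching the vectorization of the k x q score matrix's
    transpose.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    if k is None:
        k = theta.k
    elif k != theta.k:
        raise ValueError(f"k={k} does not match hyperparameters (k={theta.k})")
    q = times.size
    D = times[:, None] - times[None, :]
    nuggets = theta.nuggets
    cov = np.empty((k * q, k * q))
    for a in range(k):
        pa = theta.per_factor[a]
        for b in range(a, k):
            if a == b:
                block = auto_covariance(pa, float(nuggets[a]), D)
            else:
                block = cross_covariance(pa, theta.per_factor[b], D)
            cov[a * q:(a + 1) * q, b * q:(b + 1) * q] = block
            if b != a:
                cov[b * q:(b + 1) * q, a * q:(a + 1) * q] = block.T
    return cov


def mean_vector(theta: MOGPHyperparams, q: int) -> np.ndarray:
    """Factor-major mean vector: each constant mean c_a repeated q times."""
    return np.repeat(np.asarray(theta.means, dtype=float), q)


def cross_correlation(theta: MOGPHyperparams, a: int, b: int) -> float:
    """Zero-lag cross-correlation rho_ab between two distinct factors.

    rho_ab = C_ab(0) / sqrt(C_aa(0) * C_bb(0)), with the nugget included in the
    variances; constant across time by stationarity.
    """
    if a == b:
        raise ValueError("cross_correlation requires two distinct factors")
    nuggets = theta.nuggets
    va = stationary_variance(theta.per_factor[a], float(nuggets[a]))
    vb = stationary_variance(theta.per_factor[b], float(nuggets[b]))
    if va <= 0 or vb <= 0:
        raise ValueError("correlation undefined for a zero-variance factor")
    cab = float(cross_covariance(theta.per_factor[a], theta.per_factor[b], 0.0))
    return cab / math.sqrt(va * vb)


def cross_correlation_matrix(theta: MOGPHyperparams) -> np.ndarray:
    """k x k matrix of zero-lag factor correlations (unit diagonal)."""
    k = theta.k
    rho = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            rho[a, b] = rho[b, a] = cross_correlation(theta, a, b)
    return rho


def normalize_unit_variance(theta: MOGPHyperparams) -> tuple[MOGPHyperparams, np.ndarray]:
    """Rescale each factor so its stationary variance C_aa(0) equals one.

    Returns the normalized hyperparameters and the per-factor scale factors
    ``s_a = sqrt(C_aa(0))``.  Callers absorb ``s_a`` into column ``a`` of the
    loading matrix, leaving the product L Y (and hence the likelihood)
    unchanged; the constant means ``c_a`` are divided by ``s_a`` for the same
    reason.  Cross-correlations are invariant under this rescaling.
    """
    nuggets = theta.nuggets
    variances = np.array(
        [stationary_variance(p, float(ng)) for p, ng in zip(theta.per_factor, nuggets)]
    )
    if np.any(variances <= 0):
        raise ValueError("cannot normalize a factor with non-positive stationary variance")
    scales = np.sqrt(variances)
    new_pf = tuple(
        FactorKernelParams(v0=p.v0 / s, v1=p.v1 / s, B0=p.B0, B1=p.B1)
        for p, s in zip(theta.per_factor, scales)
    )
    new_nugget = tuple(float(ng / s**2) for ng, s in zip(nuggets, scales))
    new_means = tuple(c / s for c, s in zip(theta.means, scales))
    return MOGPHyperparams(new_pf, new_nugget, new_means), scales
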