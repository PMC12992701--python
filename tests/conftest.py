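import numpy as np
import pytest

from mogpfa import kernel, simulate
from mogpfa.model import BiomarkerPanel, LatentState, PriorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def theta_k2():
    """A normalized two-factor hyperparameter set with rho = 0.6."""
    return simulate.theta_from_correlation(
        np.array([[1.0, 0.6], [0.6, 1.0]]), B0=0.7, B1=0.7, psi2=0.1
    )


@pytest.fixture
def tiny_panel(rng):
    """n=2 subjects, p=3 biomarkers, grid of q=2 times; subject 1 misses one."""
    return BiomarkerPanel(
        subjects=["a", "b"],
        biomarkers=["g1", "g2", "g3"],
        grid=np.array([0.0, 1.5]),
        obs_idx=[np.array([0, 1]), np.array([1])],
        X=[rng.normal(size=(3, 2)), rng.normal(size=(3, 1))],
    )


@pytest.fixture
def tiny_state(tiny_panel, rng):
    k, n, p, q = 1, tiny_panel.n, tiny_panel.p, tiny_panel.q
    return LatentState(
        A=rng.normal(size=(p, k)),
        Z=np.ones((p, k), dtype=int),
        M=rng.normal(size=(n, p)),
        Yaug=rng.normal(size=(n, k, q)),
        pi=np.full(k, 0.5),
        rho2=np.ones(k),
        sigma2=np.full(p, 0.5),
        phi2=np.full(p, 0.25),
    )


@pytest.fixture
def tiny_priors(tiny_panel):
    return PriorConfig(c0=2.0, d0=2.0, c1=4.0, d1=3.0, c2=4.0, d2=3.0,
                       c3=4.0, d3=3.0, mu_g=tiny_panel.biomarker_means())


def exact_factor_conditional(panel, state, theta, i):
    """Oracle: full conditional of vec(Y_i,aug^T) by direct joint-Gaussian
    conditioning in the (k q)-dimensional space."""
    k, q = theta.k, panel.q
    sigma = kernel.build_covariance(theta, panel.grid)
    mean0 = kernel.mean_vector(theta, q)
    L = state.L
    prec_lik = np.zeros((k * q, k * q))
    G = (L / state.phi2[:, None]).T @ L
    for pos in panel.obs_idx[i]:
        for a in range(k):
            for b in range(k):
                prec_lik[a * q + pos, b * q + pos] += G[a, b]
    lin = np.zeros(k * q)
    for jj, pos in enumerate(panel.obs_idx[i]):
        contr = L.T @ ((panel.X[i][:, jj] - state.M[i]) / state.phi2)
        for a in range(k):
            lin[a * q + pos] += contr[a]
    Q = np.linalg.inv(sigma) + prec_lik
    cov = np.linalg.inv(Q)
    mean = cov @ (np.linalg.inv(sigma) @ mean0 + lin)
    return mean, cov


def make_state(panel, k, rng, sparse=False):
    n, p, q = panel.n, panel.p, panel.q
    Z = (rng.random((p, k)) < 0.4).astype(int) if sparse else np.ones((p, k), int)
    return LatentState(
        A=rng.normal(size=(p, k)),
        Z=Z,
        M=rng.normal(size=(n, p)),
        Yaug=rng.normal(size=(n, k, q)),
        pi=np.full(k, 0.3),
        rho2=np.ones(k),
        sigma2=np.full(p, 0.5),
        phi2=np.full(p, 0.25),
    )
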