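"""Signed-permutation alignment of factors.

A factor model's likelihood is invariant under jointly permuting and
sign-flipping the columns of the loading matrix L and the rows of the factor
score matrix Y ("label switching" plus "sign change").  There are 2^k * k!
such signed permutations for k factors.  This module aligns posterior draws
within and across chains to a reference draw, and aligns final estimates to a
known simulation truth by exhaustive search minimizing the mean absolute
difference (MAD) of cross-correlations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SignedPermutation",
    "enumerate_signed_permutations",
    "apply_signed_permutation",
    "align_draws",
    "align_to_truth",
    "transform_correlation",
]


@dataclass(frozen=True)
class SignedPermutation:
    """A permutation of factor indices together with per-factor sign flips.

    The transformed objects are defined by ``L'[:, a] = signs[a] * L[:, perm[a]]``
    and ``Y'[a, :] = signs[a] * Y[perm[a], :]``, so that L' Y' = L Y.
    """

    perm: tuple[int, ...]
    signs: tuple[int, ...]

    def __post_init__(self) -> None:
        k = len(self.perm)
        if sorted(self.perm) != list(range(k)):
            raise ValueError(f"perm must be a permutation of 0..{k - 1}")
        if len(self.signs) != k or any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs must be a +/-1 vector of length k")

    @property
    def k(self) -> int:
        return len(self.perm)

    @classmethod
    def identity(cls, k: int) -> "SignedPermutation":
        return cls(tuple(range(k)), (1,) * k)

    def compose(self, other: "SignedPermutation") -> "SignedPermutation":
        """The signed permutation equivalent to applying ``other`` then ``self``."""
        perm = tuple(other.perm[p] for p in self.perm)
        signs = tuple(self.signs[a] * other.signs[self.perm[a]] for a in range(self.k))
        return SignedPermutation(perm, signs)


def enumerate_signed_permutations(k: int):
    """All 2^k * k! signed permutations of k factors."""
    out = []
    for perm in itertools.permutations(range(k)):
        for signs in itertools.product((1, -1), repeat=k):
            out.append(SignedPermutation(perm, signs))
    return out


def apply_signed_permutation(sp: SignedPermutation, L: np.ndarray, Y: np.ndarray):
    """Apply a signed permutation jointly to loading columns and score rows."""
    s = np.asarray(sp.signs, dtype=float)
    perm = list(sp.perm)
    L2 = L[:, perm] * s[None, :]
    Y2 = Y[perm, :] * s.reshape((-1,) + (1,) * (Y.ndim - 1))
    return L2, Y2


def transform_correlation(sp: SignedPermutation, rho: np.ndarray) -> np.ndarray:
    """Cross-correlation matrix after a signed permutation of the factors."""
    perm = list(sp.perm)
    s = np.asarray(sp.signs, dtype=float)
    return (s[:, None] * s[None, :]) * rho[np.ix_(perm, perm)]


def _apply_to_draw(chain: dict, d: int, sp: SignedPermutation) -> None:
    s = np.asarray(sp.signs, dtype=float)
    perm = list(sp.perm)
    for name in ("L", "A"):
        chain[name][d] = chain[name][d][:, perm] * s[None, :]
    chain["Z"][d] = chain["Z"][d][:, perm]
    chain["Yaug"][d] = chain["Yaug"][d][:, perm, :] * s[None, :, None]
    for name in ("pi", "rho2"):
        chain[name][d] = chain[name][d][perm]


def align_draws(samples, reference: np.ndarray | None = None):
    """Align every retained draw (all chains) to a reference loading matrix.

    Each draw is transformed by the signed permutation minimizing the mean
    absolute difference between its loading matrix and the reference; the
    reference defaults to the draw with the highest observation
    log-likelihood across chains.  Returns the same PosteriorSamples object,
    modified in place, with alignment metadata attached.
    """
    chains = samples.chains
    if not chains or chains[0]["L"].shape[0] == 0:
        raise ValueError("no retained draws to align")
    k = chains[0]["L"].shape[2]
    if reference is None:
        best = None
        for chain in chains:
            d = int(np.argmax(chain["loglik"]))
            if best is None or chain["loglik"][d] > best[0]:
                best = (chain["loglik"][d], chain["L"][d])
        reference = best[1]
    # exhaustive search is exact and cheap at the k used here (2-5); beyond
    # k=6 fall back to a greedy column assignment
    exhaustive = k <= 6
    candidates = enumerate_signed_permutations(k) if exhaustive else None
    alignments = []
    for chain in chains:
        chain_sps = []
        for d in range(chain["L"].shape[0]):
            L = chain["L"][d]
            if exhaustive:
                costs = [
                    np.abs(
                        L[:, list(sp.perm)] * np.asarray(sp.signs)[None, :]
                        - reference
                    ).mean()
                    for sp in candidates
                ]
                sp = candidates[int(np.argmin(costs))]
            else:
                sp = _greedy_signed_match(L, reference)
            _apply_to_draw(chain, d, sp)
            chain_sps.append(sp)
        alignments.append(chain_sps)
    samples.aligned = True
    samples.alignments = alignments
    return samples


def _greedy_signed_match(L: np.ndarray, reference: np.ndarray) -> SignedPermutation:
    """Assignment-based relaxation of the exhaustive search for large k.

    Solves the column-matching problem exactly (Hungarian algorithm) with the
    per-pair cost minimized over the sign, which relaxes only the joint
    sign/permutation coupling of the exhaustive criterion.
    """
    from scipy.optimize import linear_sum_assignment

    k = L.shape[1]
    cost = np.empty((k, k))
    sign_choice = np.empty((k, k), dtype=int)
    for a in range(k):            # reference position a <- draw column b
        for b in range(k):
            plus = np.abs(L[:, b] - reference[:, a]).mean()
            minus = np.abs(-L[:, b] - reference[:, a]).mean()
            cost[a, b] = min(plus, minus)
            sign_choice[a, b] = 1 if plus <= minus else -1
    rows, cols = linear_sum_assignment(cost)
    perm = tuple(int(cols[a]) for a in range(k))
    signs = tuple(int(sign_choice[a, cols[a]]) for a in range(k))
    return SignedPermutation(perm, signs)


def best_signed_permutation(L: np.ndarray, reference: np.ndarray) -> SignedPermutation:
    """Signed permutation minimizing the mean absolute loading difference."""
    k = L.shape[1]
    best, best_cost = None, np.inf
    for sp in enumerate_signed_permutations(k):
        cost = np.abs(L[:, list(sp.perm)] * np.asarray(sp.signs)[None, :] - reference).mean()
        if cost < best_cost:
            best, best_cost = sp, cost
    return best


def apply_to_state(sp: SignedPermutation, state) -> None:
    """Relabel a latent state in place by a signed permutation of the factors.

    The observation likelihood is invariant, so this is a measure-preserving
    move used to keep a Gibbs chain in a single labeling mode.
    """
    s = np.asarray(sp.signs, dtype=float)
    perm = list(sp.perm)
    state.A = state.A[:, perm] * s[None, :]
    state.Z = state.Z[:, perm]
    state.Yaug = state.Yaug[:, perm, :] * s[None, :, None]
    state.pi = state.pi[perm]
    state.rho2 = state.rho2[perm]


def apply_to_theta(sp: SignedPermutation, theta):
    """Relabel MOGP hyperparameters: permute factors, flip shared amplitudes."""
    from .kernel import FactorKernelParams, MOGPHyperparams

    perm = list(sp.perm)
    pf = tuple(
        FactorKernelParams(
            v0=sp.signs[a] * theta.per_factor[perm[a]].v0,
            v1=theta.per_factor[perm[a]].v1,
            B0=theta.per_factor[perm[a]].B0,
            B1=theta.per_factor[perm[a]].B1,
        )
        for a in range(sp.k)
    )
    nuggets = theta.nuggets[perm]
    means = tuple(sp.signs[a] * theta.means[perm[a]] for a in range(sp.k))
    return MOGPHyperparams(pf, tuple(float(x) for x in nuggets), means)


def align_to_truth(
    L_hat: np.ndarray | None,
    rho_hat: np.ndarray,
    L_true: np.ndarray | None,
    rho_true: np.ndarray,
    k: int,
) -> tuple[SignedPermutation, float]:
    """Exhaustively align an estimate to the generating truth; return the MAD.

    Searches all 2^k * k! signed permutations for the one minimizing the mean
    absolute difference between the transformed estimated cross-correlations
    and the true ones (off-diagonal entries); ties are broken by the loading
    MAD when loadings are supplied.  Guarded at k <= 8 -- beyond that the
    enumeration is impractical and reference-based alignment should be used.
    """
    if k > 8:
        raise ValueError("k too large for exhaustive search; use align_draws instead")
    rho_hat = np.asarray(rho_hat, dtype=float)
    rho_true = np.asarray(rho_true, dtype=float)
    iu = np.triu_indices(k, 1)
    best = None
    for sp in enumerate_signed_permutations(k):
        rho_t = transform_correlation(sp, rho_hat)
        mad = float(np.abs(rho_t[iu] - rho_true[iu]).mean()) if iu[0].size else 0.0
        tie = 0.0
        if L_hat is not None and L_true is not None:
            Lt = np.asarray(L_hat)[:, list(sp.perm)] * np.asarray(sp.signs)[None, :]
            tie = float(np.abs(Lt - L_true).mean())
        key = (mad, tie)
        if best is None or key < best[0]:
            best = (key, sp)
    (mad, _), sp = best
    return sp, mad
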