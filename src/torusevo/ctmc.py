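"""Reversible continuous-time Markov chains for discrete observation pairs.

Two alphabets are used: the 20 canonical amino acids (one-letter codes in
alphabetical order) and a 3-class secondary-structure alphabet H/S/C
(helix, sheet, coil).  A chain is parameterized GTR-style by a symmetric
exchangeability matrix, an equilibrium frequency vector and a positive rate
scale: off-diagonal rates Q_ij = Λ·S_ij·π_j.  Detailed balance
π_i Q_ij = π_j Q_ji holds by construction, so pair likelihoods
π_a P_ab(t) are symmetric in (a, b) and one protein of a pair may be
treated as the ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
SS_ALPHABET = "HSC"

AA_INDEX = {c: i for i, c in enumerate(AA_ALPHABET)}
SS_INDEX = {c: i for i, c in enumerate(SS_ALPHABET)}


def encode(symbols: str, alphabet: str) -> np.ndarray:
    """Encode a symbol string to integer indices; raises on unknown symbols."""
    index = AA_INDEX if alphabet == AA_ALPHABET else {c: i for i, c in enumerate(alphabet)}
    try:
        return np.array([index[s] for s in symbols], dtype=int)
    except KeyError as e:
        raise ValueError(f"unknown state symbol {e.args[0]!r} for alphabet {alphabet!r}") from None


@dataclass
class ReversibleCTMC:
    """A time-reversible CTMC: Q = scale · S · diag(equilibrium)."""

    exchangeability: np.ndarray
    equilibrium: np.ndarray
    scale: float = 1.0
    _eig: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        S = np.asarray(self.exchangeability, dtype=float)
        pi = np.asarray(self.equilibrium, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1] or S.shape[0] != pi.shape[0]:
            raise ValueError("exchangeability/equilibrium shape mismatch")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("exchangeability matrix must be symmetric")
        if np.any(S < -1e-12) or np.any(np.abs(np.diag(S)) > 1e-12):
            raise ValueError("exchangeability must be non-negative with zero diagonal")
        if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("equilibrium must be a strictly positive probability vector")
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        self.exchangeability = S
        self.equilibrium = pi / pi.sum()
        self._eig = None

    @property
    def n_states(self) -> int:
        return len(self.equilibrium)

    def rate_matrix(self) -> np.ndarray:
        """Q with off-diagonal Q_ij = scale·S_ij·π_j and zero row sums."""
        Q = self.scale * self.exchangeability * self.equilibrium[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def _eigendecomposition(self):
        # symmetrize: B = Π^{1/2} Q Π^{−1/2} is symmetric for reversible Q
        if self._eig is None:
            Q = self.rate_matrix()
            sq = np.sqrt(self.equilibrium)
            B = (sq[:, None] * Q) / sq[None, :]
            lam, U = np.linalg.eigh(0.5 * (B + B.T))
            self._eig = (lam, U, sq)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt), exact via eigendecomposition of the symmetrized Q."""
        if t < 0:
            raise ValueError("t must be >= 0")
        if t == 0:
            return np.eye(self.n_states)
        lam, U, sq = self._eigendecomposition()
        M = (U * np.exp(lam * t)) @ U.T
        P = (M / sq[:, None]) * sq[None, :]
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)

    def pair_loglik(self, a: int, b: int, t: float) -> float:
        """log(π_a · P_ab(t)); symmetric in (a, b) by detailed balance."""
        P = self.transition_matrix(t)
        val = self.equilibrium[a] * P[a, b]
        return float(np.log(val)) if val > 0 else -np.inf

    def sample_pair(self, t: float, rng) -> tuple[int, int]:
        """Draw (a, b): a from the equilibrium, b from row a of P(t)."""
        rng = np.random.default_rng(rng)
        a = int(rng.choice(self.n_states, p=self.equilibrium))
        b = int(rng.choice(self.n_states, p=self.transition_matrix(t)[a]))
        return a, b


def build_rate_matrix(c: ReversibleCTMC) -> np.ndarray:
    return c.rate_matrix()


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """exp(Qt) for an arbitrary rate matrix (scaling-and-squaring fallback)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    from scipy.linalg import expm

    return expm(np.asarray(Q, float) * t)


def random_exchangeability(n: int, rng) -> np.ndarray:
    """A synthetic symmetric exchangeability matrix with zero diagonal."""
    rng = np.random.default_rng(rng)
    S = rng.gamma(shape=1.0, scale=1.0, size=(n, n))
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 0.0)
    return S
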