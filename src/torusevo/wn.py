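"""Bivariate wrapped-normal (WN) diffusion on the torus.

The WN diffusion is the torus analogue of the Ornstein–Uhlenbeck process:
a Euclidean OU drift toward μ, made periodic by weighting the drifts of all
2π-translates (windings) of the state, then wrapping onto T².  Its
stationary law is the wrapped bivariate normal WN(μ, ½A⁻¹Σ), and its
transition density is approximated by a tractable multimodal pseudo-tpd —
a winding-weighted mixture of wrapped Gaussians whose component means decay
toward μ as e^{−tA} and whose covariance is Γt = ∫₀ᵗ e^{−sA} Σ e^{−sAᵀ} ds.

Parameterization: Σ = diag(σ1², σ2²) and

    A = [[α1,            (σ1/σ2)·α3],
         [(σ2/σ1)·α3,    α2       ]],     α1·α2 > α3²,

which guarantees A⁻¹Σ is symmetric positive definite. α1, α2 are the drift
(mean-reversion) rates of φ and ψ; α3 couples the two angles; σ1, σ2 are
the diffusion coefficients.

Infinite winding sums over ℤ² are truncated to k ∈ {−K..K}²; the first few
terms give an accurate approximation at realistic parameter values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .torus import TWO_PI, TorusPoint, wrap_array

LOG_2PI = math.log(2.0 * math.pi)

#: Winding truncation used for likelihood evaluation.
DEFAULT_K = 1


@dataclass(frozen=True)
class WNParams:
    """Parameters of one WN diffusion: stationary mean, drifts, diffusion."""

    mu: TorusPoint
    alpha1: float
    alpha2: float
    alpha3: float
    sigma1: float
    sigma2: float

    def validate(self) -> "WNParams":
        if not (self.alpha1 > 0 and self.alpha2 > 0):
            raise ValueError("invalid WN parameters: require alpha1 > 0 and alpha2 > 0")
        if not (self.sigma1 > 0 and self.sigma2 > 0):
            raise ValueError("invalid WN parameters: require sigma1 > 0 and sigma2 > 0")
        if not self.alpha1 * self.alpha2 > self.alpha3**2:
            raise ValueError(
                "invalid WN parameters: require alpha1*alpha2 > alpha3**2 "
                f"({self.alpha1 * self.alpha2:g} <= {self.alpha3**2:g})"
            )
        return self

    @property
    def A(self) -> np.ndarray:
        r = self.sigma1 / self.sigma2
        return np.array(
            [[self.alpha1, r * self.alpha3], [self.alpha3 / r, self.alpha2]], dtype=float
        )

    @property
    def Sigma(self) -> np.ndarray:
        return np.diag([self.sigma1**2, self.sigma2**2])

    @property
    def mu_vec(self) -> np.ndarray:
        return self.mu.as_array()

    def as_dict(self) -> dict:
        return {
            "mu": [self.mu.phi, self.mu.psi],
            "alpha1": self.alpha1,
            "alpha2": self.alpha2,
            "alpha3": self.alpha3,
            "sigma1": self.sigma1,
            "sigma2": self.sigma2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WNParams":
        return cls(
            mu=TorusPoint(*d["mu"]),
            alpha1=d["alpha1"],
            alpha2=d["alpha2"],
            alpha3=d["alpha3"],
            sigma1=d["sigma1"],
            sigma2=d["sigma2"],
        ).validate()


def validate_params(p: WNParams) -> WNParams:
    """Check the positivity and α1α2 > α3² constraints; return p unchanged."""
    return p.validate()


def stationary_cov(p: WNParams) -> np.ndarray:
    """Stationary covariance ½ A⁻¹ Σ (symmetric positive definite)."""
    A, S = p.A, p.Sigma
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    Ainv = np.array([[A[1, 1], -A[0, 1]], [-A[1, 0], A[0, 0]]]) / det
    C = 0.5 * Ainv @ S
    return 0.5 * (C + C.T)  # symmetrize roundoff


@lru_cache(maxsize=8)
def _winding_offsets_cached(K: int):
    g = np.arange(-K, K + 1, dtype=float) * TWO_PI
    out = np.stack(np.meshgrid(g, g, indexing="ij"), axis=-1).reshape(-1, 2)
    out.setflags(write=False)
    return out


def winding_offsets(K: int) -> np.ndarray:
    """2π·k offsets for k ∈ {−K..K}², shape ((2K+1)², 2)."""
    return _winding_offsets_cached(int(K))


def _expm2(M: np.ndarray) -> np.ndarray:
    """Closed-form exponential of a real 2×2 matrix.

    e^M = e^m (cosh(q) I + sinh(q)/q (M − m I)) with m the mean eigenvalue
    and q² the discriminant; for the drift matrices used here q is real.
    """
    a, b, c, d = M[0, 0], M[0, 1], M[1, 0], M[1, 1]
    m = 0.5 * (a + d)
    q2 = 0.25 * (a - d) ** 2 + b * c
    if q2 >= 0:
        # fold e^m into the hyperbolic terms: for the stable matrices used
        # here m ± q ≤ 0, so these exponentials cannot overflow
        q = math.sqrt(q2)
        ep, en = math.exp(min(m + q, 700.0)), math.exp(m - q)
        ch = 0.5 * (ep + en)
        sh = 0.5 * (ep - en) / q if q > 1e-12 else math.exp(m)
    else:
        q = math.sqrt(-q2)
        em = math.exp(m)
        ch = em * math.cos(q)
        sh = em * (math.sin(q) / q if q > 1e-12 else 1.0)
    return ch * np.eye(2) + sh * (M - m * np.eye(2))


def _gauss2_logpdf(dev: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """log N(dev; 0, cov) for dev of shape (..., 2) and a 2×2 covariance."""
    a, b, c = cov[0, 0], cov[0, 1], cov[1, 1]
    det = a * c - b * b
    if det <= 0:
        raise ValueError("covariance not positive definite")
    x, y = dev[..., 0], dev[..., 1]
    quad = (c * x * x - 2.0 * b * x * y + a * y * y) / det
    return -LOG_2PI - 0.5 * math.log(det) - 0.5 * quad


def _logsumexp(a: np.ndarray, axis: int = -1) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        return np.squeeze(m, axis) + np.log(np.sum(np.exp(a - m), axis=axis))


def _points(theta) -> np.ndarray:
    if isinstance(theta, TorusPoint):
        return theta.as_array().reshape(1, 2)
    arr = np.asarray(theta, dtype=float)
    return wrap_array(arr.reshape(-1, 2))


def _maybe_scalar(out: np.ndarray, theta) -> np.ndarray | float:
    if isinstance(theta, TorusPoint) or np.asarray(theta).ndim == 1:
        return float(out[0])
    return out


def stationary_logpdf(theta, p: WNParams, K: int = DEFAULT_K):
    """Log-density of the stationary law WN(μ, ½A⁻¹Σ) at theta.

    theta may be a TorusPoint, a length-2 array, or an (n, 2) array.
    """
    pts = _points(theta)
    dev = pts[:, None, :] - p.mu_vec + winding_offsets(K)[None, :, :]
    out = _logsumexp(_gauss2_logpdf(dev, stationary_cov(p)), axis=1)
    return _maybe_scalar(out, theta)


def drift_weights(theta, p: WNParams, K: int = DEFAULT_K):
    """Winding weights w_k(θ): normalized stationary-Gaussian masses of the
    2π-translates of θ.  Non-negative, summing to 1 over the truncated set.
    Returned in the row order of :func:`winding_offsets`.
    """
    pts = _points(theta)
    dev = pts[:, None, :] - p.mu_vec + winding_offsets(K)[None, :, :]
    logw = _gauss2_logpdf(dev, stationary_cov(p))
    logw = logw - _logsumexp(logw, axis=1)[:, None]
    w = np.exp(logw)
    if isinstance(theta, TorusPoint) or np.asarray(theta).ndim == 1:
        return w[0]
    return w


def drift(theta, p: WNParams, K: int = DEFAULT_K):
    """Drift vector field A Σ_k (μ − θ − 2πk) w_k(θ): periodic, zero at μ."""
    pts = _points(theta)
    offs = winding_offsets(K)
    dev = pts[:, None, :] - p.mu_vec + offs[None, :, :]  # θ − μ + 2πk
    w = drift_weights(pts, p, K)
    if w.ndim == 1:
        w = w[None, :]
    mean_dev = np.sum(w[:, :, None] * dev, axis=1)
    out = -(mean_dev @ p.A.T)
    if isinstance(theta, TorusPoint) or np.asarray(theta).ndim == 1:
        return out[0]
    return out


def gamma_t(p: WNParams, t: float) -> np.ndarray:
    """Transition covariance Γt = ∫₀ᵗ e^{−sA} Σ e^{−sAᵀ} ds (closed form).

    Uses Γt = Γ∞ − e^{−tA} Γ∞ e^{−tAᵀ} with Γ∞ = ½A⁻¹Σ, which solves the
    Lyapunov equation A Γ∞ + Γ∞ Aᵀ = Σ for the reversible parameterization.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    Ginf = stationary_cov(p)
    if t == 0:
        return np.zeros((2, 2))
    E = _expm2(-t * p.A)
    G = Ginf - E @ Ginf @ E.T
    return 0.5 * (G + G.T)


def pseudo_tpd_logpdf(theta2, theta1, p: WNParams, t: float, K: int = DEFAULT_K):
    """Log pseudo-transition density p̃(θ2 | θ1, t).

    A mixture over windings m: component means μ + e^{−tA}(θ1 − μ + 2πm),
    common covariance Γt, weights w_m(θ1); each component is itself a
    wrapped Gaussian.  Collapses to a Dirac delta as t→0 and to the
    stationary law as t→∞.  theta1/theta2 may be paired (n, 2) arrays.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    p1 = _points(theta1)
    p2 = _points(theta2)
    if p1.shape[0] == 1 and p2.shape[0] > 1:
        p1 = np.broadcast_to(p1, p2.shape)
    if t == 0:
        same = np.all(np.isclose(wrap_array(p2 - p1), 0.0, atol=1e-12), axis=1)
        out = np.where(same, np.inf, -np.inf)
        return _maybe_scalar(out, theta2)
    offs = winding_offsets(K)
    Gt = gamma_t(p, t)
    E = _expm2(-t * p.A)
    mu = p.mu_vec
    # component means: (n, Wm, 2)
    means = mu + (p1[:, None, :] - mu + offs[None, :, :]) @ E.T
    logw = np.log(np.maximum(drift_weights(p1, p, K), 1e-300))  # (n, Wm)
    if logw.ndim == 1:
        logw = logw[None, :]
    dev = p2[:, None, None, :] - means[:, :, None, :] + offs[None, None, :, :]
    comp = _logsumexp(_gauss2_logpdf(dev, Gt), axis=2)  # (n, Wm)
    out = _logsumexp(logw + comp, axis=1)
    return _maybe_scalar(out, theta2)


def pair_loglik(x_a, x_b, p: WNParams, t: float, K: int = DEFAULT_K):
    """Log-likelihood of a homologous dihedral pair: ancestral side from the
    stationary law, descendant side from the pseudo-tpd.  Time-reversible.
    """
    return pseudo_tpd_logpdf(x_b, x_a, p, t, K) + stationary_logpdf(x_a, p, K)


def sample_stationary(p: WNParams, n: int, rng) -> np.ndarray:
    """n draws from WN(μ, ½A⁻¹Σ), as an (n, 2) array of wrapped angles."""
    rng = np.random.default_rng(rng)
    z = rng.multivariate_normal(p.mu_vec, stationary_cov(p), size=n)
    return wrap_array(z)


def sample_transition(theta1, p: WNParams, t: float, n: int, rng, K: int = DEFAULT_K) -> np.ndarray:
    """n draws from the pseudo-tpd given a single starting point theta1."""
    if t < 0:
        raise ValueError("t must be >= 0")
    rng = np.random.default_rng(rng)
    start = _points(theta1)[0]
    if t == 0:
        return np.tile(start, (n, 1))
    offs = winding_offsets(K)
    w = drift_weights(start, p, K)
    m = rng.choice(len(offs), size=n, p=w / w.sum())
    E = _expm2(-t * p.A)
    means = p.mu_vec + (start - p.mu_vec + offs[m]) @ E.T
    z = means + rng.multivariate_normal(np.zeros(2), gamma_t(p, t), size=n)
    return wrap_array(z)


def sample_transition_paired(theta1: np.ndarray, p: WNParams, t: float, rng,
                             K: int = DEFAULT_K) -> np.ndarray:
    """One pseudo-tpd draw for each row of an (n, 2) array of start points."""
    rng = np.random.default_rng(rng)
    p1 = _points(theta1)
    if t == 0:
        return p1.copy()
    offs = winding_offsets(K)
    w = drift_weights(p1, p, K)
    if w.ndim == 1:
        w = w[None, :]
    cum = np.cumsum(w, axis=1)
    u = rng.random(len(p1))[:, None]
    m = np.argmax(u < cum / cum[:, -1:], axis=1)
    E = _expm2(-t * p.A)
    means = p.mu_vec + (p1 - p.mu_vec + offs[m]) @ E.T
    z = means + rng.multivariate_normal(np.zeros(2), gamma_t(p, t), size=len(p1))
    return wrap_array(z)


def dataset_loglik(
    p: WNParams,
    pair_xa: np.ndarray,
    pair_xb: np.ndarray,
    pair_t: np.ndarray,
    singles: np.ndarray,
    K: int = DEFAULT_K,
) -> float:
    """Total log-likelihood of constant-evolution angle pairs (at
    heterogeneous times) plus one-sided stationary observations.

    Vectorized across observations and grouped by unique time; the
    winding weights of the ancestral side are computed once (they do not
    depend on t).  This is the training objective of one WN diffusion.
    """
    offs = winding_offsets(K)
    C = stationary_cov(p)
    mu = p.mu_vec
    Ginf = C
    total = 0.0
    if len(singles):
        total += float(np.sum(stationary_logpdf(singles, p, K)))
    if not len(pair_xa):
        return total
    dev_a = pair_xa[:, None, :] - mu + offs[None, :, :]  # (n, W, 2)
    g = _gauss2_logpdf(dev_a, C)
    log_stat_a = _logsumexp(g, axis=1)
    total += float(np.sum(log_stat_a))
    logw = g - log_stat_a[:, None]
    pair_t = np.asarray(pair_t, dtype=float)
    uts, inv = np.unique(pair_t, return_inverse=True)
    Es = np.stack([_expm2(-t * p.A) for t in uts])  # (T, 2, 2)
    Gts = Ginf[None] - np.einsum("tij,jk,tlk->til", Es, Ginf, Es)
    Erow, Grow = Es[inv], Gts[inv]
    means = mu + np.einsum("nwj,nij->nwi", dev_a, Erow)  # (n, W, 2)
    dev2 = pair_xb[:, None, None, :] - means[:, :, None, :] + offs[None, None, :, :]
    a = Grow[:, 0, 0][:, None, None]
    b = Grow[:, 0, 1][:, None, None]
    c = Grow[:, 1, 1][:, None, None]
    det = a * c - b * b
    if np.any(det <= 0):
        return -np.inf
    x, y = dev2[..., 0], dev2[..., 1]  # (n, W, W)
    quad = (c * x * x - 2.0 * b * x * y + a * y * y) / det
    logpdf = -LOG_2PI - 0.5 * np.log(det) - 0.5 * quad  # (n, W, W)
    n, W = logw.shape
    joint = logw[:, :, None] + logpdf  # (n, W, W)
    total += float(np.sum(_logsumexp(joint.reshape(n, W * W), axis=1)))
    return total
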