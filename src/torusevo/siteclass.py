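"""Site-classes, evolutionary hidden states, and per-site pair likelihoods.

Each evolutionary hidden state bundles two *site-classes*.  A site-class
specifies the parameters of three conditionally independent reversible
processes: an amino-acid CTMC (site-class equilibrium + rate scale over a
global exchangeability matrix), a secondary-structure CTMC, and a WN
diffusion over dihedral angles.  At a homologous site the pair either
evolved under a single class ("constant evolution", time-dependent
transition kernels) or underwent a *jump event* (the class differs between
the two proteins and both sides are drawn independently from their class's
stationary laws, independently of t).  The jump mechanism couples amino
acid changes directionally to large conformational changes.

The site-class pair prior is a two-state jump chain with rate γ and
equilibrium (π1, π2):

    p(ra | rb, t) = e^{−γt}·1[ra = rb] + π_{ra}·(1 − e^{−γt}),

which normalizes and satisfies detailed balance, so p(1,2) = p(2,1) at
every t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ctmc import AA_INDEX, SS_INDEX, ReversibleCTMC
from .observations import ObservationPair
from .torus import TorusPoint
from . import wn
from .wn import WNParams

#: Site-class pair order used everywhere: (1,1), (1,2), (2,1), (2,2).
PAIR_ORDER = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass
class SiteClass:
    """Parameter bundle of one site-class."""

    aa_equilibrium: np.ndarray  # 20-simplex
    aa_scale: float  # Λ, rate multiplier of the global exchangeability
    ss_equilibrium: np.ndarray  # 3-simplex
    wn: WNParams

    def __post_init__(self) -> None:
        self.aa_equilibrium = np.asarray(self.aa_equilibrium, dtype=float)
        self.ss_equilibrium = np.asarray(self.ss_equilibrium, dtype=float)
        for name, v, n in (("aa", self.aa_equilibrium, 20), ("ss", self.ss_equilibrium, 3)):
            if v.shape != (n,) or np.any(v <= 0) or abs(v.sum() - 1.0) > 1e-6:
                raise ValueError(f"{name}_equilibrium must be a strictly positive {n}-simplex")
        if not self.aa_scale > 0:
            raise ValueError("aa_scale must be positive")
        self.wn.validate()

    def aa_ctmc(self, global_S: np.ndarray) -> ReversibleCTMC:
        return ReversibleCTMC(global_S, self.aa_equilibrium, self.aa_scale)

    def ss_ctmc(self, global_V: np.ndarray) -> ReversibleCTMC:
        return ReversibleCTMC(global_V, self.ss_equilibrium, 1.0)


@dataclass
class HiddenState:
    """One evolutionary hidden state: two site-classes, their equilibrium
    weights (π1, π2) and the jump rate γ."""

    class1: SiteClass
    class2: SiteClass
    class_equilibrium: np.ndarray  # (π1, π2)
    jump_rate: float  # γ > 0

    def __post_init__(self) -> None:
        self.class_equilibrium = np.asarray(self.class_equilibrium, dtype=float)
        if self.class_equilibrium.shape != (2,) or np.any(self.class_equilibrium <= 0) or abs(
            self.class_equilibrium.sum() - 1.0
        ) > 1e-8:
            raise ValueError("class_equilibrium must be a strictly positive 2-simplex")
        if not self.jump_rate > 0:
            raise ValueError("jump_rate must be positive")

    @property
    def classes(self) -> tuple[SiteClass, SiteClass]:
        return (self.class1, self.class2)


def site_class_pair_probs(h: HiddenState, t: float) -> np.ndarray:
    """Joint prior over the four site-class pairs, order :data:`PAIR_ORDER`.

    Sums to 1; p(1,2) = p(2,1) at every t (time-reversibility); marginals
    equal (π1, π2); reduces to diag(π) at t = 0 and to π⊗π as t → ∞.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    pi = h.class_equilibrium
    e = math.exp(-h.jump_rate * t)
    out = np.empty(4)
    for idx, (ra, rb) in enumerate(PAIR_ORDER):
        cond = (e if ra == rb else 0.0) + pi[ra] * (1.0 - e)
        out[idx] = cond * pi[rb]
    return out


# ---------------------------------------------------------------------------
# scalar per-site likelihoods (reference implementations; the vectorized
# engine in hmm.py is cross-checked against these)


def _pair_factor_discrete(a, b, ctmc: ReversibleCTMC, t: float) -> float:
    if a is None and b is None:
        return 0.0
    if a is not None and b is not None:
        return ctmc.pair_loglik(a, b, t)
    s = a if a is not None else b
    return float(np.log(ctmc.equilibrium[s]))


def _stat_factor_discrete(s, ctmc: ReversibleCTMC) -> float:
    return 0.0 if s is None else float(np.log(ctmc.equilibrium[s]))


def _codes(o: ObservationPair):
    aa_a = None if o.aa_a is None else AA_INDEX[o.aa_a]
    aa_b = None if o.aa_b is None else AA_INDEX[o.aa_b]
    ss_a = None if o.ss_a is None else SS_INDEX[o.ss_a]
    ss_b = None if o.ss_b is None else SS_INDEX[o.ss_b]
    return aa_a, aa_b, ss_a, ss_b


def obs_pair_loglik_constant(
    o: ObservationPair, sc: SiteClass, t: float, global_S, global_V, K: int = wn.DEFAULT_K
) -> float:
    """Constant-evolution log-likelihood of a homologous column under one
    site-class: sum of the three factor log-likelihoods, each dropped when
    missing on both sides and replaced by the observed side's stationary
    log-density when missing on one side."""
    aa_a, aa_b, ss_a, ss_b = _codes(o)
    ll = _pair_factor_discrete(aa_a, aa_b, sc.aa_ctmc(global_S), t)
    ll += _pair_factor_discrete(ss_a, ss_b, sc.ss_ctmc(global_V), t)
    if o.x_a is not None and o.x_b is not None:
        if t == 0:
            # delta-mass convention at t = 0 (unit transition mass on equality)
            same = (abs(o.x_a.phi - o.x_b.phi) < 1e-9
                    and abs(o.x_a.psi - o.x_b.psi) < 1e-9)
            ll += (float(wn.stationary_logpdf(o.x_a, sc.wn, K)) if same else -math.inf)
        else:
            ll += float(wn.pair_loglik(o.x_a, o.x_b, sc.wn, t, K))
    elif o.x_a is not None:
        ll += float(wn.stationary_logpdf(o.x_a, sc.wn, K))
    elif o.x_b is not None:
        ll += float(wn.stationary_logpdf(o.x_b, sc.wn, K))
    return ll


def _side_stationary_loglik(
    aa, x, ss, sc: SiteClass, global_S, global_V, K: int = wn.DEFAULT_K
) -> float:
    ll = _stat_factor_discrete(aa, sc.aa_ctmc(global_S))
    ll += _stat_factor_discrete(ss, sc.ss_ctmc(global_V))
    if x is not None:
        ll += float(wn.stationary_logpdf(x, sc.wn, K))
    return ll


def obs_pair_loglik_jump(
    o: ObservationPair, sc_a: SiteClass, sc_b: SiteClass, global_S, global_V,
    K: int = wn.DEFAULT_K,
) -> float:
    """Jump-event log-likelihood: each side independently from the stationary
    laws of its own site-class.  Independent of t."""
    aa_a, aa_b, ss_a, ss_b = _codes(o)
    ll = _side_stationary_loglik(aa_a, o.x_a, ss_a, sc_a, global_S, global_V, K)
    ll += _side_stationary_loglik(aa_b, o.x_b, ss_b, sc_b, global_S, global_V, K)
    return ll


def _branch_logliks(
    o: ObservationPair, h: HiddenState, t: float, global_S, global_V, K: int
) -> np.ndarray:
    """Log-likelihood of the column under each of the four site-class pairs."""
    out = np.empty(4)
    for idx, (ra, rb) in enumerate(PAIR_ORDER):
        if ra == rb:
            out[idx] = obs_pair_loglik_constant(o, h.classes[ra], t, global_S, global_V, K)
        else:
            out[idx] = obs_pair_loglik_jump(
                o, h.classes[ra], h.classes[rb], global_S, global_V, K
            )
    return out


def obs_pair_loglik(
    o: ObservationPair, h: HiddenState, t: float, global_S, global_V, K: int = wn.DEFAULT_K
) -> float:
    """Marginal log-likelihood of one column given a hidden state: the
    mixture over the four site-class pairs (constant branches when ra = rb,
    jump branches otherwise).  Non-homologous columns contribute the
    single-sided stationary mixture Σ_r π_r · L_r(observed side)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if not o.homologous:
        pi = h.class_equilibrium
        a_side = any(v is not None for v in (o.aa_a, o.x_a, o.ss_a))
        terms = []
        for r, sc in enumerate(h.classes):
            if a_side:
                ll = _side_stationary_loglik(
                    _codes(o)[0], o.x_a, _codes(o)[2], sc, global_S, global_V, K
                )
            else:
                ll = _side_stationary_loglik(
                    _codes(o)[1], o.x_b, _codes(o)[3], sc, global_S, global_V, K
                )
            terms.append(math.log(pi[r]) + ll)
        return float(wn._logsumexp(np.array(terms)[None, :], axis=1)[0])
    prior = site_class_pair_probs(h, t)
    branch = _branch_logliks(o, h, t, global_S, global_V, K)
    with np.errstate(divide="ignore"):
        terms = np.log(prior) + branch
    return float(wn._logsumexp(terms[None, :], axis=1)[0])


def posterior_site_class_pair(
    o: ObservationPair, h: HiddenState, t: float, global_S, global_V, K: int = wn.DEFAULT_K
) -> np.ndarray:
    """Bayes posterior over the four site-class pairs given the column."""
    prior = site_class_pair_probs(h, t)
    branch = _branch_logliks(o, h, t, global_S, global_V, K)
    with np.errstate(divide="ignore"):
        logpost = np.log(prior) + branch
    logpost -= logpost.max()
    post = np.exp(logpost)
    return post / post.sum()


def sample_site(
    h: HiddenState, t: float, rng, global_S, global_V,
    condition: ObservationPair | None = None, K: int = wn.DEFAULT_K,
    return_latent: bool = False,
):
    """Draw a complete homologous column given a hidden state.

    Without conditioning, the site-class pair is drawn from its prior; with
    a partial column, from its posterior, and observed fields are kept.
    Constant branch: ancestral side from the stationary laws, descendant
    from the transition kernels; jump branch: both sides from their own
    class's stationary laws.
    """
    rng = np.random.default_rng(rng)
    from .ctmc import AA_ALPHABET, SS_ALPHABET

    if condition is None:
        condition = ObservationPair()
    probs = (
        site_class_pair_probs(h, t)
        if all(
            v is None
            for v in (condition.aa_a, condition.aa_b, condition.x_a, condition.x_b,
                      condition.ss_a, condition.ss_b)
        )
        else posterior_site_class_pair(condition, h, t, global_S, global_V, K)
    )
    ra, rb = PAIR_ORDER[int(rng.choice(4, p=probs))]
    sc_a, sc_b = h.classes[ra], h.classes[rb]
    aa_a, aa_b, ss_a, ss_b = _codes(condition)

    def _discrete(a, b, ctmc_a: ReversibleCTMC, ctmc_b: ReversibleCTMC, jump: bool):
        if jump:
            if a is None:
                a = int(rng.choice(ctmc_a.n_states, p=ctmc_a.equilibrium))
            if b is None:
                b = int(rng.choice(ctmc_b.n_states, p=ctmc_b.equilibrium))
            return a, b
        c = ctmc_a
        if a is None and b is None:
            a = int(rng.choice(c.n_states, p=c.equilibrium))
        if a is not None and b is None:
            b = int(rng.choice(c.n_states, p=c.transition_matrix(t)[a]))
        elif b is not None and a is None:
            a = int(rng.choice(c.n_states, p=c.transition_matrix(t)[b]))
        return a, b

    jump = ra != rb
    aa_a, aa_b = _discrete(aa_a, aa_b, sc_a.aa_ctmc(global_S), sc_b.aa_ctmc(global_S), jump)
    ss_a, ss_b = _discrete(ss_a, ss_b, sc_a.ss_ctmc(global_V), sc_b.ss_ctmc(global_V), jump)
    x_a, x_b = condition.x_a, condition.x_b
    if jump:
        if x_a is None:
            x_a = TorusPoint(*wn.sample_stationary(sc_a.wn, 1, rng)[0])
        if x_b is None:
            x_b = TorusPoint(*wn.sample_stationary(sc_b.wn, 1, rng)[0])
    else:
        if x_a is None and x_b is None:
            x_a = TorusPoint(*wn.sample_stationary(sc_a.wn, 1, rng)[0])
        if x_a is not None and x_b is None:
            x_b = TorusPoint(*wn.sample_transition(x_a, sc_a.wn, t, 1, rng, K)[0])
        elif x_b is not None and x_a is None:
            x_a = TorusPoint(*wn.sample_transition(x_b, sc_a.wn, t, 1, rng, K)[0])
    out = ObservationPair(
        aa_a=AA_ALPHABET[aa_a], aa_b=AA_ALPHABET[aa_b],
        x_a=x_a, x_b=x_b,
        ss_a=SS_ALPHABET[ss_a], ss_b=SS_ALPHABET[ss_b],
    )
    return (out, (ra, rb)) if return_latent else out
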