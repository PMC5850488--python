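"""The evolutionary hidden-Markov model over aligned sites, for a FIXED
pairwise alignment.

Hidden nodes run along the alignment; horizontal transitions encode
neighboring dependencies (e.g. helix-like states following helix-like
states).  Each hidden state emits one aligned column through the site-class
pair mixture of :mod:`torusevo.siteclass`.  This module provides the
likelihood (forward), per-site posteriors (forward–backward), posterior
jump probabilities, conditional imputation of missing observations
(forward-filter backward-sample), and full generative simulation.

The initial hidden distribution is the stationary distribution of the
transition matrix, keeping the chain marginally homogeneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import wn
from .ctmc import ReversibleCTMC
from .observations import PairObservations
from .siteclass import PAIR_ORDER, site_class_pair_probs
from .torus import wrap_array


def _logsumexp(a: np.ndarray, axis: int = -1) -> np.ndarray:
    return wn._logsumexp(a, axis=axis)


@dataclass
class EvolutionaryModel:
    """h evolutionary hidden states + HMM transition structure + global
    amino-acid and secondary-structure exchangeability matrices."""

    states: list
    transition: np.ndarray
    global_aa_exchangeability: np.ndarray
    global_ss_exchangeability: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        h = len(self.states)
        if h < 1:
            raise ValueError("need at least one hidden state")
        if self.transition.shape != (h, h) or np.any(self.transition < 0) or not np.allclose(
            self.transition.sum(axis=1), 1.0, atol=1e-8
        ):
            raise ValueError("transition must be an h×h row-stochastic matrix")
        self.global_aa_exchangeability = np.asarray(self.global_aa_exchangeability, float)
        self.global_ss_exchangeability = np.asarray(self.global_ss_exchangeability, float)
        for name, M, n in (
            ("amino-acid", self.global_aa_exchangeability, 20),
            ("secondary-structure", self.global_ss_exchangeability, 3),
        ):
            if M.shape != (n, n) or not np.allclose(M, M.T, atol=1e-8):
                raise ValueError(f"global {name} exchangeability must be symmetric {n}×{n}")
        self._cache = {}

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def initial(self) -> np.ndarray:
        """Stationary distribution of the transition matrix."""
        key = "initial"
        if key not in self._cache:
            vals, vecs = np.linalg.eig(self.transition.T)
            i = int(np.argmin(np.abs(vals - 1.0)))
            v = np.real(vecs[:, i])
            v = np.abs(v)
            self._cache[key] = v / v.sum()
        return self._cache[key]

    def aa_ctmc(self, k: int, r: int) -> ReversibleCTMC:
        key = ("aa", k, r)
        if key not in self._cache:
            self._cache[key] = self.states[k].classes[r].aa_ctmc(self.global_aa_exchangeability)
        return self._cache[key]

    def ss_ctmc(self, k: int, r: int) -> ReversibleCTMC:
        key = ("ss", k, r)
        if key not in self._cache:
            self._cache[key] = self.states[k].classes[r].ss_ctmc(self.global_ss_exchangeability)
        return self._cache[key]


def _as_pair_obs(obs) -> PairObservations:
    if isinstance(obs, PairObservations):
        return obs
    return PairObservations.from_sites(list(obs))


# ---------------------------------------------------------------------------
# vectorized emission table


def _discrete_pair_ll(a: np.ndarray, b: np.ndarray, ctmc: ReversibleCTMC, t: float):
    """(pair_ll, stat_a, stat_b) arrays for coded tracks with −1 missing."""
    logpi = np.log(ctmc.equilibrium)
    both = (a >= 0) & (b >= 0)
    out = np.zeros(len(a))
    if np.any(both):
        with np.errstate(divide="ignore"):
            logP = np.log(np.maximum(ctmc.transition_matrix(t), 0.0))
        out[both] = logpi[a[both]] + logP[a[both], b[both]]
    only_a = (a >= 0) & (b < 0)
    only_b = (b >= 0) & (a < 0)
    out[only_a] = logpi[a[only_a]]
    out[only_b] = logpi[b[only_b]]
    stat_a = np.where(a >= 0, logpi[np.maximum(a, 0)], 0.0)
    stat_b = np.where(b >= 0, logpi[np.maximum(b, 0)], 0.0)
    return out, stat_a, stat_b


def _angle_pair_ll(xa: np.ndarray, xb: np.ndarray, params, t: float, K: int):
    ok_a = np.all(np.isfinite(xa), axis=1)
    ok_b = np.all(np.isfinite(xb), axis=1)
    m = len(xa)
    pair = np.zeros(m)
    stat_a = np.zeros(m)
    stat_b = np.zeros(m)
    if np.any(ok_a):
        stat_a[ok_a] = np.atleast_1d(wn.stationary_logpdf(xa[ok_a], params, K))
    if np.any(ok_b):
        stat_b[ok_b] = np.atleast_1d(wn.stationary_logpdf(xb[ok_b], params, K))
    both = ok_a & ok_b
    if np.any(both):
        if t == 0:
            # delta-mass convention: the t = 0 transition kernel puts unit
            # mass on equality, so equal pairs keep the ancestral density
            from .torus import wrap_array as _wrap

            same = np.all(np.abs(_wrap(xa[both] - xb[both])) < 1e-9, axis=1)
            pair[both] = np.where(same, stat_a[both], -np.inf)
        else:
            pair[both] = np.atleast_1d(
                wn.pseudo_tpd_logpdf(xb[both], xa[both], params, t, K)
            ) + stat_a[both]
    only_a = ok_a & ~ok_b
    only_b = ok_b & ~ok_a
    pair[only_a] = stat_a[only_a]
    pair[only_b] = stat_b[only_b]
    return pair, stat_a, stat_b


@dataclass
class EmissionTable:
    """Per-site, per-state emission quantities for one aligned pair."""

    log_e: np.ndarray  # (m, h) column log-likelihood given hidden state
    branch: np.ndarray  # (h, m, 4) log-lik of each site-class pair branch
    log_prior: np.ndarray  # (h, 4) log site-class pair prior
    stat_a: np.ndarray  # (h, m, 2) one-sided stationary log-liks, side a
    stat_b: np.ndarray
    homologous: np.ndarray  # (m,) bool


def compute_emissions(
    model: EvolutionaryModel, obs: PairObservations, t: float, K: int = wn.DEFAULT_K
) -> EmissionTable:
    """Build the emission table for all sites and hidden states at time t."""
    if t < 0:
        raise ValueError("t must be >= 0")
    m, h = obs.n_sites, model.n_states
    const = np.zeros((h, m, 2))
    stat_a = np.zeros((h, m, 2))
    stat_b = np.zeros((h, m, 2))
    for k in range(h):
        for r in range(2):
            sc = model.states[k].classes[r]
            pa, sa_a, sa_b = _discrete_pair_ll(obs.aa_a, obs.aa_b, model.aa_ctmc(k, r), t)
            ps, ss_a, ss_b = _discrete_pair_ll(obs.ss_a, obs.ss_b, model.ss_ctmc(k, r), t)
            px, sx_a, sx_b = _angle_pair_ll(obs.x_a, obs.x_b, sc.wn, t, K)
            const[k, :, r] = pa + ps + px
            stat_a[k, :, r] = sa_a + ss_a + sx_a
            stat_b[k, :, r] = sa_b + ss_b + sx_b
    branch = np.empty((h, m, 4))
    for idx, (ra, rb) in enumerate(PAIR_ORDER):
        if ra == rb:
            branch[:, :, idx] = const[:, :, ra]
        else:
            branch[:, :, idx] = stat_a[:, :, ra] + stat_b[:, :, rb]
    log_prior = np.empty((h, 4))
    with np.errstate(divide="ignore"):
        for k in range(h):
            log_prior[k] = np.log(site_class_pair_probs(model.states[k], t))
    log_e = _logsumexp(log_prior[:, None, :] + branch, axis=2).T  # (m, h)
    hom = obs.homologous
    if not np.all(hom):
        # indel columns: single-sided mixture over the two site-classes
        logpi = np.array([np.log(s.class_equilibrium) for s in model.states])  # (h, 2)
        single = _logsumexp(
            logpi[:, None, :] + stat_a[:, :, :] + stat_b[:, :, :], axis=2
        ).T  # (m, h); absent side contributes 0
        log_e = np.where(hom[:, None], log_e, single)
    return EmissionTable(log_e, branch, log_prior, stat_a, stat_b, hom.copy())


# ---------------------------------------------------------------------------
# forward / backward


def _forward(table: EmissionTable, model: EvolutionaryModel):
    with np.errstate(divide="ignore"):
        logT = np.log(np.maximum(model.transition, 0.0))
        log_init = np.log(model.initial)
    m = table.log_e.shape[0]
    f = np.empty_like(table.log_e)
    f[0] = log_init + table.log_e[0]
    for i in range(1, m):
        f[i] = _logsumexp(f[i - 1][:, None] + logT, axis=0) + table.log_e[i]
    return f, float(_logsumexp(f[-1][None, :], axis=1)[0])


def forward_loglik(obs, model: EvolutionaryModel, t: float, K: int = wn.DEFAULT_K) -> float:
    """log p(observations | model, t) for a fixed alignment (all sites)."""
    obs = _as_pair_obs(obs)
    if obs.n_sites == 0:
        raise ValueError("empty observation sequence")
    table = compute_emissions(model, obs, t, K)
    return _forward(table, model)[1]


def posterior_hidden(obs, model: EvolutionaryModel, t: float, K: int = wn.DEFAULT_K) -> np.ndarray:
    """(m, h) posterior over hidden states per site (forward–backward)."""
    obs = _as_pair_obs(obs)
    table = compute_emissions(model, obs, t, K)
    return _posterior_hidden_from_table(table, model)


def _backward(table: EmissionTable, model: EvolutionaryModel):
    with np.errstate(divide="ignore"):
        logT = np.log(np.maximum(model.transition, 0.0))
    m, h = table.log_e.shape
    b = np.zeros((m, h))
    for i in range(m - 2, -1, -1):
        b[i] = _logsumexp(logT + (table.log_e[i + 1] + b[i + 1])[None, :], axis=1)
    return b


def _posterior_hidden_from_table(table: EmissionTable, model: EvolutionaryModel) -> np.ndarray:
    f, total = _forward(table, model)
    b = _backward(table, model)
    post = np.exp(f + b - total)
    return post / post.sum(axis=1, keepdims=True)


def posterior_jump(obs, model: EvolutionaryModel, t: float, K: int = wn.DEFAULT_K) -> np.ndarray:
    """(m, h) joint posterior p(H_i = k, ra ≠ rb | observations).

    Zero at non-homologous columns (a jump is defined only for homologous
    sites).  Summing over k and adding the no-jump complement gives 1.
    """
    obs = _as_pair_obs(obs)
    table = compute_emissions(model, obs, t, K)
    ph = _posterior_hidden_from_table(table, model)  # (m, h)
    logpost = table.log_prior[:, None, :] + table.branch  # (h, m, 4)
    logpost = logpost - _logsumexp(logpost, axis=2)[:, :, None]
    p_jump_given_state = np.exp(_logsumexp(logpost[:, :, 1:3], axis=2)).T  # (m, h)
    out = ph * p_jump_given_state
    out[~table.homologous] = 0.0
    return out


# ---------------------------------------------------------------------------
# sampling


def _sample_categorical_rows(p: np.ndarray, rng) -> np.ndarray:
    """One draw per row of a row-stochastic matrix."""
    cum = np.cumsum(p, axis=1)
    u = rng.random(len(p))[:, None]
    return np.argmax(u < cum / cum[:, -1:], axis=1)


def sample_hidden_path(table: EmissionTable, model: EvolutionaryModel, rng) -> np.ndarray:
    """Forward-filter backward-sample one hidden path."""
    rng = np.random.default_rng(rng)
    f, _ = _forward(table, model)
    with np.errstate(divide="ignore"):
        logT = np.log(np.maximum(model.transition, 0.0))
    m, h = f.shape
    path = np.empty(m, dtype=int)
    w = f[-1] - f[-1].max()
    p = np.exp(w)
    path[-1] = rng.choice(h, p=p / p.sum())
    for i in range(m - 2, -1, -1):
        w = f[i] + logT[:, path[i + 1]]
        w -= w.max()
        p = np.exp(w)
        path[i] = rng.choice(h, p=p / p.sum())
    return path


def _sample_branches(table: EmissionTable, path: np.ndarray, rng) -> np.ndarray:
    """Site-class pair index per site from its posterior given the path."""
    m = len(path)
    logpost = table.log_prior[path] + table.branch[path, np.arange(m)]  # (m, 4)
    logpost -= logpost.max(axis=1, keepdims=True)
    p = np.exp(logpost)
    return _sample_categorical_rows(p / p.sum(axis=1, keepdims=True), rng)


def _impute_discrete(obs, track_a, track_b, get_ctmc, path, ra, rb, jump, t, rng):
    """Fill missing entries of one discrete track pair, grouped by state/class.

    Constant-evolution sites use the transition kernel given an observed
    partner (either direction, by reversibility); jump sites and indel
    columns draw from the class's stationary law.  Sides without a residue
    are never filled.
    """
    a, b = track_a, track_b
    hom = obs.homologous
    for k in np.unique(path):
        for r in range(2):
            c = get_ctmc(k, r)
            eq = c.equilibrium
            # jump branch or indel column: missing side from its own class stationary
            sel_a = (a < 0) & obs.has_a & (path == k) & (ra == r) & (jump | ~hom)
            sel_b = (b < 0) & obs.has_b & (path == k) & (rb == r) & (jump | ~hom)
            if np.any(sel_a):
                a[sel_a] = rng.choice(c.n_states, size=int(sel_a.sum()), p=eq)
            if np.any(sel_b):
                b[sel_b] = rng.choice(c.n_states, size=int(sel_b.sum()), p=eq)
            # constant branch (homologous columns only)
            const = (~jump) & (path == k) & (ra == r) & hom
            none = const & (a < 0) & (b < 0)
            if np.any(none):
                a[none] = rng.choice(c.n_states, size=int(none.sum()), p=eq)
            P = c.transition_matrix(t)
            need_b = const & (a >= 0) & (b < 0)
            if np.any(need_b):
                b[need_b] = _sample_categorical_rows(P[a[need_b]], rng)
            need_a = const & (b >= 0) & (a < 0)
            if np.any(need_a):
                a[need_a] = _sample_categorical_rows(P[b[need_a]], rng)
    return a, b


def _impute_angles(obs, xa, xb, model, path, ra, rb, jump, t, rng, K):
    ok_a = np.all(np.isfinite(xa), axis=1)
    ok_b = np.all(np.isfinite(xb), axis=1)
    hom = obs.homologous
    for k in np.unique(path):
        for r in range(2):
            params = model.states[k].classes[r].wn
            sel_a = ~ok_a & obs.has_a & (path == k) & (ra == r) & (jump | ~hom)
            sel_b = ~ok_b & obs.has_b & (path == k) & (rb == r) & (jump | ~hom)
            if np.any(sel_a):
                xa[sel_a] = wn.sample_stationary(params, int(sel_a.sum()), rng)
            if np.any(sel_b):
                xb[sel_b] = wn.sample_stationary(params, int(sel_b.sum()), rng)
            const = (~jump) & (path == k) & (ra == r) & hom
            none = const & ~ok_a & ~ok_b
            if np.any(none):
                xa[none] = wn.sample_stationary(params, int(none.sum()), rng)
                ok_a = ok_a | none
            need_b = const & ok_a & ~ok_b
            if np.any(need_b):
                xb[need_b] = wn.sample_transition_paired(xa[need_b], params, t, rng, K)
            need_a = const & ok_b & ~ok_a
            if np.any(need_a):
                xa[need_a] = wn.sample_transition_paired(xb[need_a], params, t, rng, K)
    return xa, xb


def _complete_given_latents(
    obs: PairObservations, model: EvolutionaryModel, t: float,
    path: np.ndarray, branch_idx: np.ndarray, rng, K: int,
) -> PairObservations:
    out = obs.copy()
    pairs = np.array(PAIR_ORDER)
    ra, rb = pairs[branch_idx, 0], pairs[branch_idx, 1]
    jump = ra != rb
    _impute_discrete(out, out.aa_a, out.aa_b, model.aa_ctmc, path, ra, rb, jump, t, rng)
    _impute_discrete(out, out.ss_a, out.ss_b, model.ss_ctmc, path, ra, rb, jump, t, rng)
    _impute_angles(out, out.x_a, out.x_b, model, path, ra, rb, jump, t, rng, K)
    return out


def sample_missing(
    obs, model: EvolutionaryModel, t: float, n_samples: int, rng, K: int = wn.DEFAULT_K
) -> list[PairObservations]:
    """Impute missing observation fields conditional on the observed ones.

    Each sample draws a hidden path by forward-filter backward-sampling,
    then a site-class pair per site from its posterior, then fills each
    missing field from its conditional: the transition kernel given the
    observed partner under constant evolution, the class stationary law
    under a jump.  Observed fields are never altered.
    """
    rng = np.random.default_rng(rng)
    obs = _as_pair_obs(obs)
    table = compute_emissions(model, obs, t, K)
    out = []
    for _ in range(n_samples):
        path = sample_hidden_path(table, model, rng)
        branch_idx = _sample_branches(table, path, rng)
        out.append(_complete_given_latents(obs, model, t, path, branch_idx, rng, K))
    return out


def simulate_pair(
    model: EvolutionaryModel, length: int, t: float, rng,
    K: int = wn.DEFAULT_K, return_latent: bool = False,
):
    """Simulate a fully observed homologous pair of the given length."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if t < 0:
        raise ValueError("t must be >= 0")
    rng = np.random.default_rng(rng)
    h = model.n_states
    path = np.empty(length, dtype=int)
    path[0] = rng.choice(h, p=model.initial)
    for i in range(1, length):
        path[i] = rng.choice(h, p=model.transition[path[i - 1]])
    probs = np.array([site_class_pair_probs(model.states[k], t) for k in range(h)])
    branch_idx = _sample_categorical_rows(probs[path], rng)
    empty = PairObservations.empty(length)
    obs = _complete_given_latents(empty, model, t, path, branch_idx, rng, K)
    if return_latent:
        return obs, path, branch_idx
    return obs
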