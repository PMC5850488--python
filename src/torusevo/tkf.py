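"""TKF92 statistical alignment augmented with the evolutionary hidden states.

The TKF92 fragment insertion–deletion process defines a prior over pairwise
alignments: sequences are composed of unbreakable fragments of geometric
length (extension probability r); fragments are born at rate λ and die at
rate μ > λ.  The induced pair-HMM has Match/Delete/Insert states with the
classic TKF91 β/γ transition functions between fragments and a self-loop r
within fragments; r = 0 recovers TKF91.

The alignment pair-HMM is combined with the evolutionary HMM: the dynamic
program runs over (position in a, position in b, alignment state, hidden
state).  Hidden-state transitions apply between consecutive emitted columns
regardless of column type; homologous columns emit the site-class pair
mixture, indel columns emit single-sided stationary mixtures.  Marginal
likelihoods sum over all alignments and hidden paths in
O(|p_a|·|p_b|·h²); MAP alignments use the Viterbi recursion and alignment
samples a stochastic backtrace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import wn
from .hmm import EvolutionaryModel, _logsumexp
from .observations import PairObservations, SideObservations
from .siteclass import PAIR_ORDER, site_class_pair_probs

# alignment pair-HMM state order used throughout
STATES = ("S", "M", "D", "I")  # start, match, delete, insert
M, D, I = 1, 2, 3
COLUMN_TYPES = {"M": 0, "D": 1, "I": 2}


@dataclass(frozen=True)
class TKF92Params:
    """Birth rate λ, death rate μ > λ, fragment extension probability r."""

    birth_rate: float
    death_rate: float
    fragment_extension: float = 0.5

    def validate(self) -> "TKF92Params":
        if not 0 < self.birth_rate < self.death_rate:
            raise ValueError("require 0 < birth_rate < death_rate (finite expected length)")
        if not 0 <= self.fragment_extension < 1:
            raise ValueError("fragment_extension must lie in [0, 1)")
        return self

    @classmethod
    def from_mean_length(cls, mean_length: float, fragment_extension: float = 0.5,
                         death_rate: float = 1.0) -> "TKF92Params":
        """Match E[len] = κ/(1−κ)·1/(1−r) to the data's mean sequence length."""
        r = fragment_extension
        frag = mean_length * (1.0 - r)  # expected number of fragments
        kappa = frag / (1.0 + frag)
        return cls(kappa * death_rate, death_rate, r).validate()


def tkf91_transitions(lam: float, mu: float, t: float) -> np.ndarray:
    """TKF91 pair-HMM transitions: rows S,M,D,I → columns M,D,I,End."""
    kappa = lam / mu
    alpha = math.exp(-mu * t)
    if t == 0:
        beta = 0.0
        gamma = 0.0
    else:
        e = math.exp((lam - mu) * t)
        beta = lam * (1.0 - e) / (mu - lam * e)
        gamma = 1.0 - mu * (1.0 - e) / ((1.0 - alpha) * (mu - lam * e))
    out = np.empty((4, 4))
    for row, eps in ((0, beta), (1, beta), (2, gamma), (3, beta)):
        out[row] = [(1 - eps) * kappa * alpha, (1 - eps) * kappa * (1 - alpha),
                    eps, (1 - eps) * (1 - kappa)]
    return out


def tkf92_transitions(p: TKF92Params, t: float) -> np.ndarray:
    """TKF92 pair-HMM transition probabilities.

    Rows S,M,D,I → columns M,D,I,End.  Within-fragment extension adds a
    self-loop r to each emitting state and scales the between-fragment
    (TKF91) transitions by 1−r; the start state has no fragment to extend.
    Every row sums to 1.
    """
    p.validate()
    if t < 0:
        raise ValueError("t must be >= 0")
    base = tkf91_transitions(p.birth_rate, p.death_rate, t)
    r = p.fragment_extension
    out = base.copy()
    out[1:] *= 1.0 - r
    out[1, 0] += r  # M → M
    out[2, 1] += r  # D → D
    out[3, 2] += r  # I → I
    return out


@dataclass
class PairAlignment:
    """An ordered list of alignment columns (type, index_a, index_b).

    type ∈ {"M", "D", "I"}; indices are 1-based, None on the gapped side.
    The index projections onto each protein are strictly increasing and
    cover 1..length exactly once.
    """

    columns: list
    len_a: int = None
    len_b: int = None

    def __post_init__(self) -> None:
        ia = [c[1] for c in self.columns if c[0] in ("M", "D")]
        ib = [c[2] for c in self.columns if c[0] in ("M", "I")]
        if ia != list(range(1, len(ia) + 1)) or ib != list(range(1, len(ib) + 1)):
            raise ValueError("alignment indices must be 1..n, strictly increasing")
        for c in self.columns:
            if c[0] not in COLUMN_TYPES:
                raise ValueError(f"unknown column type {c[0]!r}")
        if self.len_a is None:
            self.len_a = len(ia)
        if self.len_b is None:
            self.len_b = len(ib)
        if self.len_a != len(ia) or self.len_b != len(ib):
            raise ValueError("alignment does not cover the sequences")

    def __len__(self) -> int:
        return len(self.columns)

    def __eq__(self, other) -> bool:
        return isinstance(other, PairAlignment) and self.columns == other.columns

    def __hash__(self) -> int:
        return hash(tuple(self.columns))

    @property
    def column_types(self) -> str:
        return "".join(c[0] for c in self.columns)

    @classmethod
    def from_state_string(cls, states: str) -> "PairAlignment":
        """Build from a column-type string like 'MMDIM'."""
        cols, ia, ib = [], 0, 0
        for s in states:
            if s == "M":
                ia, ib = ia + 1, ib + 1
                cols.append(("M", ia, ib))
            elif s == "D":
                ia += 1
                cols.append(("D", ia, None))
            elif s == "I":
                ib += 1
                cols.append(("I", None, ib))
            else:
                raise ValueError(f"unknown column type {s!r}")
        return cls(cols)

    @classmethod
    def from_gapped(cls, row_a: str, row_b: str) -> "PairAlignment":
        """Build from two equal-length gapped sequence rows ('-' = gap)."""
        if len(row_a) != len(row_b):
            raise ValueError("gapped rows must have equal length")
        states = []
        for ca, cb in zip(row_a, row_b):
            if ca != "-" and cb != "-":
                states.append("M")
            elif ca != "-":
                states.append("D")
            elif cb != "-":
                states.append("I")
            else:
                raise ValueError("column with gaps on both sides")
        return cls.from_state_string("".join(states))

    def homologous_pairs(self) -> set:
        return {(c[1], c[2]) for c in self.columns if c[0] == "M"}

    def column_set(self) -> set:
        return set(self.columns)


def project_columns(alignment: PairAlignment, side_a: SideObservations,
                    side_b: SideObservations) -> PairObservations:
    """Assemble aligned PairObservations from two protein tracks."""
    if alignment.len_a != side_a.n_residues or alignment.len_b != side_b.n_residues:
        raise ValueError("alignment/sequence length mismatch")
    m = len(alignment)
    obs = PairObservations.empty(m)
    for i, (typ, ia, ib) in enumerate(alignment.columns):
        obs.col_type[i] = COLUMN_TYPES[typ]
        if ia is not None:
            obs.aa_a[i] = side_a.aa[ia - 1]
            obs.x_a[i] = side_a.x[ia - 1]
            obs.ss_a[i] = side_a.ss[ia - 1]
        if ib is not None:
            obs.aa_b[i] = side_b.aa[ib - 1]
            obs.x_b[i] = side_b.x[ib - 1]
            obs.ss_b[i] = side_b.ss[ib - 1]
    return obs


# ---------------------------------------------------------------------------
# emission tables for the alignment DP


def _class_tables(model: EvolutionaryModel, side_a: SideObservations,
                  side_b: SideObservations, t: float, K: int):
    """Per (state, class): cross-product constant log-liks (la, lb) and
    one-sided stationary log-liks (la,) / (lb,)."""
    h = model.n_states
    la, lb = side_a.n_residues, side_b.n_residues
    const = np.zeros((h, 2, la, lb))
    stat_a = np.zeros((h, 2, la))
    stat_b = np.zeros((h, 2, lb))
    ok_xa = np.all(np.isfinite(side_a.x), axis=1)
    ok_xb = np.all(np.isfinite(side_b.x), axis=1)
    for k in range(h):
        for r in range(2):
            sc = model.states[k].classes[r]
            for (ctmc, trk_a, trk_b) in (
                (model.aa_ctmc(k, r), side_a.aa, side_b.aa),
                (model.ss_ctmc(k, r), side_a.ss, side_b.ss),
            ):
                logpi = np.log(ctmc.equilibrium)
                with np.errstate(divide="ignore"):
                    logP = np.log(np.maximum(ctmc.transition_matrix(t), 0.0))
                sa = np.where(trk_a >= 0, logpi[np.maximum(trk_a, 0)], 0.0)
                sb = np.where(trk_b >= 0, logpi[np.maximum(trk_b, 0)], 0.0)
                stat_a[k, r] += sa
                stat_b[k, r] += sb
                both = (trk_a[:, None] >= 0) & (trk_b[None, :] >= 0)
                pair = np.where(
                    both,
                    logpi[np.maximum(trk_a, 0)][:, None]
                    + logP[np.maximum(trk_a, 0)[:, None], np.maximum(trk_b, 0)[None, :]],
                    sa[:, None] + sb[None, :],
                )
                const[k, r] += pair
            # dihedral factor
            sxa = np.zeros(la)
            sxb = np.zeros(lb)
            if np.any(ok_xa):
                sxa[ok_xa] = np.atleast_1d(wn.stationary_logpdf(side_a.x[ok_xa], sc.wn, K))
            if np.any(ok_xb):
                sxb[ok_xb] = np.atleast_1d(wn.stationary_logpdf(side_b.x[ok_xb], sc.wn, K))
            stat_a[k, r] += sxa
            stat_b[k, r] += sxb
            pair = sxa[:, None] + sxb[None, :]
            if np.any(ok_xa) and np.any(ok_xb):
                ii, jj = np.nonzero(ok_xa[:, None] & ok_xb[None, :])
                tpd = np.atleast_1d(
                    wn.pseudo_tpd_logpdf(side_b.x[jj], side_a.x[ii], sc.wn, t, K)
                )
                pair[ii, jj] = tpd + sxa[ii]
            const[k, r] += pair
    return const, stat_a, stat_b


def _emission_tables(model: EvolutionaryModel, side_a, side_b, t, K):
    """emisM (la, lb, h), emisD (la, h), emisI (lb, h)."""
    h = model.n_states
    const, stat_a, stat_b = _class_tables(model, side_a, side_b, t, K)
    log_prior = np.empty((h, 4))
    logpi = np.empty((h, 2))
    with np.errstate(divide="ignore"):
        for k in range(h):
            log_prior[k] = np.log(site_class_pair_probs(model.states[k], t))
            logpi[k] = np.log(model.states[k].class_equilibrium)
    la, lb = stat_a.shape[2], stat_b.shape[2]
    branch = np.empty((h, 4, la, lb))
    for idx, (ra, rb) in enumerate(PAIR_ORDER):
        if ra == rb:
            branch[:, idx] = const[:, ra]
        else:
            branch[:, idx] = stat_a[:, ra, :, None] + stat_b[:, rb, None, :]
    emisM = _logsumexp(log_prior[:, :, None, None] + branch, axis=1)  # (h, la, lb)
    emisM = np.moveaxis(emisM, 0, 2)  # (la, lb, h)
    emisD = _logsumexp(logpi[:, :, None] + stat_a, axis=1).T  # (la, h)
    emisI = _logsumexp(logpi[:, :, None] + stat_b, axis=1).T  # (lb, h)
    return emisM, emisD, emisI


# ---------------------------------------------------------------------------
# dynamic programs


def _prep(model, p, t):
    with np.errstate(divide="ignore"):
        logT = np.log(np.maximum(tkf92_transitions(p, t), 0.0))  # rows S,M,D,I; cols M,D,I,End
        logH = np.log(np.maximum(model.transition, 0.0))
        log_init = np.log(model.initial)
    return logT, logH, log_init


def _dp(side_a, side_b, model, p, t, K, viterbi: bool):
    """Forward (sum) or Viterbi (max) DP over (i, j, align-state, hidden)."""
    emisM, emisD, emisI = _emission_tables(model, side_a, side_b, t, K)
    logT, logH, log_init = _prep(model, p, t)
    la, lb, h = emisM.shape
    NEG = -np.inf
    F = np.full((la + 1, lb + 1, 3, h), NEG)  # states M, D, I

    def reduce_mix(x):  # x: (3, h) source-state values; returns per-source hidden-mixed
        if viterbi:
            return (x[:, :, None] + logH[None, :, :]).max(axis=1)  # (3, h)
        return _logsumexp(x[:, :, None] + logH[None, :, :], axis=1)

    def incoming(i, j, target):
        """Message into a column of the given target state emitted after cell (i, j)."""
        col = 1 + target  # row index of source M/D/I in logT is 1,2,3; target col 0,1,2
        if i == 0 and j == 0:
            return logT[0, target] + log_init
        x = F[i, j]  # (3, h)
        mixed = reduce_mix(x) + logT[1:, target][:, None]
        if viterbi:
            return mixed.max(axis=0)
        return _logsumexp(mixed, axis=0)

    for i in range(la + 1):
        for j in range(lb + 1):
            if i > 0 and j > 0:
                F[i, j, 0] = emisM[i - 1, j - 1] + incoming(i - 1, j - 1, 0)
            if i > 0:
                F[i, j, 1] = emisD[i - 1] + incoming(i - 1, j, 1)
            if j > 0:
                F[i, j, 2] = emisI[j - 1] + incoming(i, j - 1, 2)
    end = F[la, lb] + logT[1:, 3][:, None]
    if viterbi:
        total = float(end.max())
    else:
        total = float(_logsumexp(end.reshape(1, -1), axis=1)[0])
    return F, end, total, (logT, logH, log_init)


def alignment_forward(side_a: SideObservations, side_b: SideObservations,
                      model: EvolutionaryModel, p: TKF92Params, t: float,
                      K: int = wn.DEFAULT_K) -> float:
    """Log marginal likelihood, summing over all alignments (TKF92 prior)
    and all hidden paths."""
    if side_a.n_residues == 0 or side_b.n_residues == 0:
        raise ValueError("both sequences must be non-empty")
    return _dp(side_a, side_b, model, p, t, K, viterbi=False)[2]


def _backtrace_step(F, logT, logH, log_init, i, j, s, k, rng, viterbi):
    """Distribution over predecessor (s', k') of a column (s, k) emitted
    after cell (i, j); returns sampled/argmax (s', k'), or None for start."""
    if i == 0 and j == 0:
        return None
    w = F[i, j] + logT[1:, s][:, None] + logH[:, k][None, :]  # (3, h) source values
    flat = w.ravel()
    if viterbi:
        idx = int(np.argmax(flat))
    else:
        pr = np.exp(flat - flat.max())
        pr /= pr.sum()
        idx = int(rng.choice(len(flat), p=pr))
    return divmod(idx, F.shape[3])


def _trace(F, end, aux, la, lb, rng, viterbi):
    logT, logH, log_init = aux
    flat = end.ravel()
    if viterbi:
        idx = int(np.argmax(flat))
    else:
        pr = np.exp(flat - flat.max())
        pr /= pr.sum()
        idx = int(rng.choice(len(flat), p=pr))
    s, k = divmod(idx, F.shape[3])
    i, j = la, lb
    cols = []
    while True:
        typ = "MDI"[s]
        cols.append((typ, i if typ in ("M", "D") else None, j if typ in ("M", "I") else None))
        if typ == "M":
            pi, pj = i - 1, j - 1
        elif typ == "D":
            pi, pj = i - 1, j
        else:
            pi, pj = i, j - 1
        prev = _backtrace_step(F, logT, logH, log_init, pi, pj, s, k, rng, viterbi)
        i, j = pi, pj
        if prev is None:
            break
        s, k = prev
    cols.reverse()
    return PairAlignment(cols)


def map_alignment(side_a, side_b, model, p: TKF92Params, t: float,
                  K: int = wn.DEFAULT_K) -> PairAlignment:
    """Most probable (alignment, hidden path) by the Viterbi recursion;
    deterministic (no RNG)."""
    F, end, _, aux = _dp(side_a, side_b, model, p, t, K, viterbi=True)
    return _trace(F, end, aux, side_a.n_residues, side_b.n_residues, None, viterbi=True)


def sample_alignments(side_a, side_b, model, p: TKF92Params, t: float, n: int, rng,
                      K: int = wn.DEFAULT_K) -> list[PairAlignment]:
    """n posterior alignment samples by stochastic backtrace."""
    rng = np.random.default_rng(rng)
    F, end, _, aux = _dp(side_a, side_b, model, p, t, K, viterbi=False)
    return [
        _trace(F, end, aux, side_a.n_residues, side_b.n_residues, rng, viterbi=False)
        for _ in range(n)
    ]


def alignment_log_prior(alignment: PairAlignment, p: TKF92Params, t: float) -> float:
    """TKF92 log prior of one alignment path (including the End transition)."""
    with np.errstate(divide="ignore"):
        logT = np.log(np.maximum(tkf92_transitions(p, t), 0.0))
    s = 0
    ll = 0.0
    for typ, _, _ in alignment.columns:
        tgt = COLUMN_TYPES[typ]
        ll += logT[s, tgt]
        s = tgt + 1
    ll += logT[s, 3]
    return float(ll)


def sample_alignment_prior(p: TKF92Params, t: float, rng,
                           min_len: int = 1, max_tries: int = 1000) -> PairAlignment:
    """Draw an alignment structure from the TKF92 prior (both sides ≥ min_len)."""
    rng = np.random.default_rng(rng)
    T = tkf92_transitions(p, t)
    for _ in range(max_tries):
        s = 0
        states = []
        while True:
            nxt = int(rng.choice(4, p=T[s]))
            if nxt == 3:
                break
            states.append("MDI"[nxt])
            s = nxt + 1
        aln = PairAlignment.from_state_string("".join(states)) if states else None
        if aln is not None and aln.len_a >= min_len and aln.len_b >= min_len:
            return aln
    raise RuntimeError("failed to sample an alignment with the requested minimum length")


# ---------------------------------------------------------------------------
# evaluation metrics


def alignment_similarity(pred: PairAlignment, ref: PairAlignment) -> float:
    """2·|shared columns| / (|pred| + |ref|); 1 iff the column sets coincide."""
    if pred.len_a != ref.len_a or pred.len_b != ref.len_b:
        raise ValueError("alignments cover different sequence lengths")
    shared = len(pred.column_set() & ref.column_set())
    return 2.0 * shared / (len(pred) + len(ref))


def homology_precision(pred: PairAlignment, ref: PairAlignment) -> float:
    """Fraction of predicted homologous site pairs that are in the reference."""
    if pred.len_a != ref.len_a or pred.len_b != ref.len_b:
        raise ValueError("alignments cover different sequence lengths")
    pp = pred.homologous_pairs()
    if not pp:
        raise ValueError("prediction contains no homologous pairs; precision undefined")
    return len(pp & ref.homologous_pairs()) / len(pp)
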