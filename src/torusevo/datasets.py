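"""Synthetic study conditions: a realistic example model and simulators.

The example model plays the role of a trained model at desk scale.  Its
three hidden states emulate the dominant regions of the Ramachandran plot
— right-handed α-helix, β-sheet, and a coil-like state whose second
site-class concentrates on glycine with a left-handed-helix mode (so that
jumps in the coil state couple a glycine exchange to a large conformational
change, the motif pattern the jump mechanism is designed to express).
Amino-acid and secondary-structure equilibria are biased toward the
residues and labels typical of each conformation; the global
exchangeability matrices are synthetic (seeded), since simulation only
requires a fixed reversible process, not database-derived rates.
"""

from __future__ import annotations

import numpy as np

from .ctmc import AA_ALPHABET, random_exchangeability
from .hmm import EvolutionaryModel, simulate_pair
from .observations import PairObservations
from .siteclass import HiddenState, SiteClass
from .tkf import TKF92Params, sample_alignment_prior
from .torus import TorusPoint
from .wn import WNParams


def _aa_freq(favored: str, weight: float = 6.0) -> np.ndarray:
    w = np.ones(20)
    for c in favored:
        w[AA_ALPHABET.index(c)] = weight
    return w / w.sum()


def _wn(mu_phi, mu_psi, a1=2.0, a2=2.0, a3=0.3, s1=0.45, s2=0.45) -> WNParams:
    return WNParams(TorusPoint(mu_phi, mu_psi), a1, a2, a3, s1, s2).validate()


def example_model(seed: int = 1234) -> EvolutionaryModel:
    """A 3-state model with helix-, sheet- and coil-like hidden states."""
    helix = HiddenState(
        SiteClass(_aa_freq("AELKQM"), 1.0, np.array([0.86, 0.04, 0.10]),
                  _wn(-1.10, -0.80, s1=0.35, s2=0.35)),
        SiteClass(_aa_freq("AELKQH", 4.0), 1.3, np.array([0.70, 0.05, 0.25]),
                  _wn(-1.35, -0.25, s1=0.40, s2=0.40)),
        class_equilibrium=np.array([0.75, 0.25]),
        jump_rate=1.5,
    )
    sheet = HiddenState(
        SiteClass(_aa_freq("VIYFTW"), 0.9, np.array([0.05, 0.85, 0.10]),
                  _wn(-2.20, 2.40, s1=0.45, s2=0.40)),
        SiteClass(_aa_freq("VITSC", 4.0), 1.2, np.array([0.08, 0.62, 0.30]),
                  _wn(-1.55, 2.55, s1=0.50, s2=0.45)),
        class_equilibrium=np.array([0.70, 0.30]),
        jump_rate=2.0,
    )
    coil = HiddenState(
        SiteClass(_aa_freq("DNSPKTQ", 4.0), 1.4, np.array([0.10, 0.10, 0.80]),
                  _wn(-1.60, 0.15, s1=0.55, s2=0.60)),
        SiteClass(_aa_freq("GN", 10.0), 1.4, np.array([0.08, 0.07, 0.85]),
                  _wn(1.00, 0.45, s1=0.45, s2=0.50)),
        class_equilibrium=np.array([0.69, 0.31]),
        jump_rate=8.0,
    )
    T = np.array([
        [0.88, 0.04, 0.08],
        [0.04, 0.86, 0.10],
        [0.10, 0.12, 0.78],
    ])
    rng = np.random.default_rng(seed)
    S = random_exchangeability(20, rng)
    S /= S[np.triu_indices(20, 1)].mean()
    V = np.array([
        [0.0, 0.4, 1.2],
        [0.4, 0.0, 1.0],
        [1.2, 1.0, 0.0],
    ])
    return EvolutionaryModel([helix, sheet, coil], T, S, V)


def default_tkf92(mean_length: float = 100.0) -> TKF92Params:
    return TKF92Params.from_mean_length(mean_length, fragment_extension=0.5)


def simulate_fixed_pairs(model, n_pairs: int, length: int, rng,
                         t_low: float = 0.1, t_high: float = 1.0):
    """Simulate homologous-only (fixed-alignment) pairs at times drawn
    log-uniformly from [t_low, t_high].  Returns (pairs, times)."""
    rng = np.random.default_rng(rng)
    ts = np.exp(rng.uniform(np.log(t_low), np.log(t_high), size=n_pairs))
    pairs = [simulate_pair(model, length, float(t), rng) for t in ts]
    return pairs, ts


def simulate_indel_pair(model, tkf: TKF92Params, t: float, rng,
                        min_len: int = 5) -> tuple[PairObservations, "object"]:
    """Simulate a pair with indels: alignment structure from the TKF92
    prior, then observations along the columns.  Returns (obs, alignment)."""
    rng = np.random.default_rng(rng)
    from .hmm import PAIR_ORDER, _complete_given_latents, _sample_categorical_rows
    from .siteclass import site_class_pair_probs

    aln = sample_alignment_prior(tkf, t, rng, min_len=min_len)
    m = len(aln)
    h = model.n_states
    path = np.empty(m, dtype=int)
    path[0] = rng.choice(h, p=model.initial)
    for i in range(1, m):
        path[i] = rng.choice(h, p=model.transition[path[i - 1]])
    probs = np.array([site_class_pair_probs(model.states[k], t) for k in range(h)])
    branch_idx = _sample_categorical_rows(probs[path], rng)
    empty = PairObservations.empty(m)
    empty.col_type[:] = [{"M": 0, "D": 1, "I": 2}[c[0]] for c in aln.columns]
    obs = _complete_given_latents(empty, model, t, path, branch_idx, rng, 1)
    return obs, aln
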