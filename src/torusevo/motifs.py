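"""Jump-event ("evolutionary motif") detection and prediction benchmarks.

A site carries evidence of an evolutionary motif when the joint posterior
of a single hidden state together with a site-class jump exceeds a primary
threshold given both sequences and both dihedral tracks, AND the same
joint posterior exceeds a secondary threshold when only one of the two
dihedral tracks is available (either side suffices).  The second criterion
keeps motifs identifiable in the common setting where only one structure
of a pair is known.  Defaults: 0.90 / 0.50, strict inequalities.

The prediction benchmark treats the dihedral angles of protein b as
missing and imputes them under the model conditioned on one of six data
combinations; accuracy is the mean angular distance between imputed and
true angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import wn
from .hmm import EvolutionaryModel, posterior_jump, sample_missing
from .observations import PairObservations, split_sides
from .torus import angular_distance_tracks

#: Track selections of the six benchmark combinations (the dihedral angles
#: of protein b are always held out).  Combination 6 additionally fixes the
#: alignment a priori.
COMBINATIONS = {
    1: dict(aa_a=False, aa_b=False, x_a=False, x_b=False, ss_a=False, ss_b=False),
    2: dict(aa_a=False, aa_b=True, x_a=False, x_b=False, ss_a=False, ss_b=False),
    3: dict(aa_a=True, aa_b=True, x_a=False, x_b=False, ss_a=False, ss_b=False),
    4: dict(aa_a=True, aa_b=True, x_a=False, x_b=False, ss_a=True, ss_b=False),
    5: dict(aa_a=True, aa_b=True, x_a=True, x_b=False, ss_a=False, ss_b=False),
    6: dict(aa_a=True, aa_b=True, x_a=True, x_b=False, ss_a=False, ss_b=False),
}


@dataclass(frozen=True)
class JumpSite:
    site: int  # 0-based alignment column
    state: int
    posterior_full: float
    posterior_a_only: float
    posterior_b_only: float


def detect_jump_sites(
    obs: PairObservations,
    model: EvolutionaryModel,
    t: float,
    primary_threshold: float = 0.90,
    secondary_threshold: float = 0.50,
    K: int = wn.DEFAULT_K,
) -> list[JumpSite]:
    """Scan an aligned pair for sites with posterior evidence of a jump.

    Requires both amino-acid tracks and both dihedral tracks at the
    homologous columns.  A site is reported when for some hidden state k
    p(H_i = k, jump | A_a, A_b, X_a, X_b) > primary_threshold and the same
    joint posterior recomputed with one dihedral track dropped exceeds
    secondary_threshold for at least one of the two sides.
    """
    hom = obs.homologous
    base = obs.mask_tracks(ss_a=False, ss_b=False)
    if (np.any(base.aa_a[hom] < 0) or np.any(base.aa_b[hom] < 0)
            or np.any(~np.isfinite(base.x_a[hom])) or np.any(~np.isfinite(base.x_b[hom]))):
        raise ValueError("jump detection requires both sequences and both dihedral tracks")
    full = posterior_jump(base, model, t, K)
    a_only = posterior_jump(base.mask_tracks(x_b=False), model, t, K)
    b_only = posterior_jump(base.mask_tracks(x_a=False), model, t, K)
    out = []
    for i in range(obs.n_sites):
        if not hom[i]:
            continue
        for k in range(model.n_states):
            if full[i, k] > primary_threshold and (
                a_only[i, k] > secondary_threshold or b_only[i, k] > secondary_threshold
            ):
                out.append(JumpSite(i, k, float(full[i, k]),
                                    float(a_only[i, k]), float(b_only[i, k])))
    return out


def _true_angles_b(pair: PairObservations) -> np.ndarray:
    """True (φ, ψ) track of protein b in residue order."""
    return pair.x_b[pair.has_b]


def predict_benchmark(
    pair: PairObservations,
    model: EvolutionaryModel,
    combination: int,
    t: float,
    n_samples: int = 20,
    seed: int = 0,
    tkf=None,
    K: int = wn.DEFAULT_K,
) -> float:
    """Mean angular distance between imputed and true dihedral angles of
    protein b under one of the six observation combinations.

    Combinations 1–5 treat the alignment as unobserved: each sample draws
    an alignment from its posterior under the TKF92 prior given the
    conditioned tracks, then imputes the missing angles given that
    alignment.  Combination 6 conditions on the given alignment.
    """
    if combination not in COMBINATIONS:
        raise ValueError("combination must be in 1..6")
    rng = np.random.default_rng(seed)
    truth = _true_angles_b(pair)
    if not np.all(np.isfinite(truth)):
        raise ValueError("benchmark requires true dihedral angles for protein b")
    keep = COMBINATIONS[combination]
    if combination == 6:
        cond = pair.mask_tracks(**keep)
        samples = sample_missing(cond, model, t, n_samples, rng, K)
        dists = [
            float(np.mean(angular_distance_tracks(_true_angles_b(s), truth)))
            for s in samples
        ]
        return float(np.mean(dists))
    from .tkf import TKF92Params, project_columns, sample_alignments

    side_a, side_b = split_sides(pair)
    if tkf is None:
        tkf = TKF92Params.from_mean_length(
            0.5 * (side_a.n_residues + side_b.n_residues)
        )
    side_a = side_a.mask_tracks(aa=keep["aa_a"], x=keep["x_a"], ss=keep["ss_a"])
    side_b = side_b.mask_tracks(aa=keep["aa_b"], x=keep["x_b"], ss=keep["ss_b"])
    alns = sample_alignments(side_a, side_b, model, tkf, t, n_samples,
                             rng, K)
    dists = []
    for aln in alns:
        cond = project_columns(aln, side_a, side_b)
        imputed = sample_missing(cond, model, t, 1, rng, K)[0]
        dists.append(float(np.mean(
            angular_distance_tracks(_true_angles_b(imputed), truth)
        )))
    return float(np.mean(dists))
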