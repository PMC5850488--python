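import itertools
import math

import numpy as np
import pytest

from torusevo import ObservationPair, PairObservations, TorusPoint
from torusevo.ctmc import AA_ALPHABET
from torusevo.hmm import forward_loglik, simulate_pair
from torusevo.observations import SideObservations, split_sides
from torusevo.tkf import (
    PairAlignment,
    TKF92Params,
    alignment_forward,
    alignment_log_prior,
    alignment_similarity,
    homology_precision,
    map_alignment,
    project_columns,
    sample_alignments,
    tkf92_transitions,
)

TKF = TKF92Params(birth_rate=0.08, death_rate=0.1, fragment_extension=0.4)


def _tkf91_reference(lam, mu, t):
    """Independent TKF91 pair-HMM formulas (birth-death of single links)."""
    kappa = lam / mu
    alpha = math.exp(-mu * t)
    e = math.exp((lam - mu) * t)
    beta = lam * (1 - e) / (mu - lam * e)
    gamma = 1 - mu * (1 - e) / ((1 - alpha) * (mu - lam * e))
    rows = {}
    for src, eps in (("S", beta), ("M", beta), ("D", gamma), ("I", beta)):
        rows[src] = {
            "M": (1 - eps) * kappa * alpha,
            "D": (1 - eps) * kappa * (1 - alpha),
            "I": eps,
            "End": (1 - eps) * (1 - kappa),
        }
    return rows


class TestTransitions:
    def test_rows_normalize(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            mu = float(rng.uniform(0.05, 2.0))
            lam = mu * float(rng.uniform(0.1, 0.95))
            r = float(rng.uniform(0.0, 0.95))
            t = float(rng.uniform(0.01, 5.0))
            T = tkf92_transitions(TKF92Params(lam, mu, r), t)
            assert np.all(T >= 0) and np.all(T <= 1)
            assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)

    def test_r_zero_reduces_to_tkf91(self):
        lam, mu, t = 0.07, 0.1, 0.6
        T = tkf92_transitions(TKF92Params(lam, mu, 0.0), t)
        ref = _tkf91_reference(lam, mu, t)
        order = ["M", "D", "I", "End"]
        for i, src in enumerate(["S", "M", "D", "I"]):
            for j, dst in enumerate(order):
                assert T[i, j] == pytest.approx(ref[src][dst], abs=1e-12), (src, dst)

    def test_zero_time_forbids_indels(self):
        T = tkf92_transitions(TKF, 0.0)
        # indel states cannot be entered from Start or Match at t = 0 (the
        # residual self-loops are unreachable), so any alignment containing
        # an indel column has zero prior probability
        assert T[0, 1] == T[0, 2] == T[1, 1] == T[1, 2] == 0.0
        with_indel = PairAlignment.from_state_string("MDIM")
        assert alignment_log_prior(with_indel, TKF, 0.0) == -np.inf
        pure = PairAlignment.from_state_string("MMM")
        assert np.isfinite(alignment_log_prior(pure, TKF, 0.0))

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            TKF92Params(0.2, 0.1).validate()
        with pytest.raises(ValueError):
            TKF92Params(0.05, 0.1, 1.0).validate()


class TestPairAlignment:
    def test_index_invariants_enforced(self):
        with pytest.raises(ValueError):
            PairAlignment([("M", 1, 1), ("M", 3, 2)])
        aln = PairAlignment.from_state_string("MMDIM")
        assert aln.len_a == 4 and aln.len_b == 4
        assert aln.columns[2] == ("D", 3, None)

    def test_gapped_round_trip(self):
        aln = PairAlignment.from_gapped("AC-DE", "A-GDE")
        assert aln.column_types == "MDIMM"
        with pytest.raises(ValueError):
            PairAlignment.from_gapped("A-", "A-")


def _enumerate_alignments(la, lb):
    """All pair-HMM paths projecting onto sequences of lengths la, lb."""
    out = []

    def rec(i, j, cols):
        if i == la and j == lb:
            out.append(PairAlignment.from_state_string("".join(cols)))
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, cols + ["M"])
        if i < la:
            rec(i + 1, j, cols + ["D"])
        if j < lb:
            rec(i, j + 1, cols + ["I"])

    rec(0, 0, [])
    return out


def _sides(rng, n, m):
    def one(n):
        return SideObservations(
            aa=rng.integers(0, 20, n),
            x=rng.uniform(-np.pi, np.pi, (n, 2)),
            ss=rng.integers(0, 3, n),
        )

    return one(n), one(m)


def _enumerated_marginal(side_a, side_b, model, p, t):
    terms = []
    for aln in _enumerate_alignments(side_a.n_residues, side_b.n_residues):
        obs = project_columns(aln, side_a, side_b)
        terms.append(alignment_log_prior(aln, p, t) + forward_loglik(obs, model, t))
    return terms


class TestAlignmentForward:
    def test_one_by_one_enumeration(self, model2):
        rng = np.random.default_rng(1)
        sa, sb = _sides(rng, 1, 1)
        terms = _enumerated_marginal(sa, sb, model2, TKF, 0.4)
        assert len(terms) == 3  # M ; D·I ; I·D
        expect = np.logaddexp.reduce(terms)
        got = alignment_forward(sa, sb, model2, TKF, 0.4)
        assert got == pytest.approx(expect, abs=1e-8)

    @pytest.mark.parametrize("t", [0.2, 1.0])
    def test_two_by_two_enumeration(self, model2, t):
        rng = np.random.default_rng(2)
        sa, sb = _sides(rng, 2, 2)
        terms = _enumerated_marginal(sa, sb, model2, TKF, t)
        expect = np.logaddexp.reduce(terms)
        got = alignment_forward(sa, sb, model2, TKF, t)
        assert got == pytest.approx(expect, abs=1e-8)

    def test_dominates_single_alignment(self, model2):
        rng = np.random.default_rng(3)
        sa, sb = _sides(rng, 4, 5)
        total = alignment_forward(sa, sb, model2, TKF, 0.5)
        aln = map_alignment(sa, sb, model2, TKF, 0.5)
        obs = project_columns(aln, sa, sb)
        single = alignment_log_prior(aln, TKF, 0.5) + forward_loglik(obs, model2, 0.5)
        assert total >= single - 1e-9

    def test_empty_sequences_rejected(self, model2):
        sa = SideObservations.blank(0)
        sb = SideObservations.blank(3)
        with pytest.raises(ValueError):
            alignment_forward(sa, sb, model2, TKF, 0.4)


class TestMAPAlignment:
    def test_identical_sequences_tiny_time_align_diagonally(self, model3):
        obs = simulate_pair(model3, 12, 0.0, 4)
        sa, sb = split_sides(obs)
        aln = map_alignment(sa, sb, model3, TKF, 0.01)
        assert aln.column_types == "M" * 12

    def test_matches_enumerated_argmax(self, model1):
        # h = 1 makes the joint Viterbi the exact alignment MAP
        rng = np.random.default_rng(5)
        sa, sb = _sides(rng, 2, 3)
        best, best_val = None, -np.inf
        for aln in _enumerate_alignments(2, 3):
            obs = project_columns(aln, sa, sb)
            v = alignment_log_prior(aln, TKF, 0.5) + forward_loglik(obs, model1, 0.5)
            if v > best_val:
                best, best_val = aln, v
        assert map_alignment(sa, sb, model1, TKF, 0.5) == best

    def test_deterministic(self, model2):
        rng = np.random.default_rng(6)
        sa, sb = _sides(rng, 5, 6)
        a1 = map_alignment(sa, sb, model2, TKF, 0.7)
        a2 = map_alignment(sa, sb, model2, TKF, 0.7)
        assert a1 == a2


class TestSampleAlignments:
    def test_tiny_instance_frequencies_match_posterior(self, model1):
        rng = np.random.default_rng(7)
        sa, sb = _sides(rng, 1, 1)
        alns = _enumerate_alignments(1, 1)
        logp = []
        for aln in alns:
            obs = project_columns(aln, sa, sb)
            logp.append(alignment_log_prior(aln, TKF, 0.5)
                        + forward_loglik(obs, model1, 0.5))
        post = np.exp(logp - np.logaddexp.reduce(logp))
        n = 20_000
        samples = sample_alignments(sa, sb, model1, TKF, 0.5, n, 0)
        for aln, p in zip(alns, post):
            freq = sum(s == aln for s in samples) / n
            se = math.sqrt(p * (1 - p) / n)
            assert abs(freq - p) < 3 * se + 1e-12, (aln.column_types, freq, p)
        # the MAP alignment is also the most frequent sample
        map_aln = map_alignment(sa, sb, model1, TKF, 0.5)
        assert map_aln == alns[int(np.argmax(post))]

    def test_seed_reproducible(self, model2):
        rng = np.random.default_rng(8)
        sa, sb = _sides(rng, 4, 4)
        s1 = sample_alignments(sa, sb, model2, TKF, 0.5, 5, 123)
        s2 = sample_alignments(sa, sb, model2, TKF, 0.5, 5, 123)
        assert s1 == s2


class TestMetrics:
    def test_similarity_extremes(self):
        ref = PairAlignment.from_state_string("MMMM")
        assert alignment_similarity(ref, ref) == 1.0
        # shift all pairings by one via indels: no shared columns
        other = PairAlignment.from_state_string("DMMMI")
        assert alignment_similarity(other, ref) == 0.0

    def test_similarity_hand_count(self):
        # ref = M11 M22 D3, pred = M11 D2 M32: the only shared column is
        # (M,1,1), so the similarity is 2·1 / (3 + 3) = 1/3
        ref = PairAlignment.from_state_string("MMD")
        pred = PairAlignment.from_state_string("MDM")
        assert alignment_similarity(pred, ref) == pytest.approx(1 / 3)
        assert alignment_similarity(ref, pred) == pytest.approx(1 / 3)

    def test_precision_definition_and_oracle(self):
        ref = PairAlignment.from_state_string("MMMM")
        # pred pairs {11, 32, 44}: only 11 and 44 are in the reference
        pred = PairAlignment.from_state_string("MDMIM")
        assert pred.homologous_pairs() == {(1, 1), (3, 2), (4, 4)}
        assert homology_precision(pred, ref) == pytest.approx(2 / 3)
        assert homology_precision(ref, ref) == 1.0
        # set-arithmetic oracle: permuting the column multiset preserves the
        # sequence lengths, so any two permutations are comparable
        rng = np.random.default_rng(9)
        for _ in range(20):
            states = list("MM") + list(rng.choice(list("MDI"), size=6))
            pred = PairAlignment.from_state_string("".join(states))
            r2 = PairAlignment.from_state_string(
                "".join(rng.permutation(states)))
            pp, rp = pred.homologous_pairs(), r2.homologous_pairs()
            assert homology_precision(pred, r2) == len(pp & rp) / len(pp)

    def test_precision_undefined_without_homologous_pairs(self):
        ref = PairAlignment.from_state_string("M")
        pred = PairAlignment.from_state_string("DI")
        with pytest.raises(ValueError):
            homology_precision(pred, ref)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            alignment_similarity(PairAlignment.from_state_string("MM"),
                                 PairAlignment.from_state_string("M"))


class TestStructuralInformationHelps:
    def test_angles_never_hurt_true_alignment_posterior(self, model3):
        # on simulated tiny instances the generating alignment's posterior
        # should (in tendency) increase when dihedral angles are added
        from torusevo.datasets import simulate_indel_pair

        rng = np.random.default_rng(11)
        tkf_sim = TKF92Params(0.45, 0.5, 0.3)
        wins = ties = losses = 0
        n_inst = 60
        for i in range(n_inst):
            obs, truth = None, None
            while truth is None or not (3 <= truth.len_a <= 10 and 3 <= truth.len_b <= 10):
                obs, truth = simulate_indel_pair(model3, tkf_sim, 0.4,
                                                 rng.integers(2**31), min_len=3)
            sa, sb = split_sides(obs)

            def true_post(side_a, side_b):
                o = project_columns(truth, side_a, side_b)
                joint = alignment_log_prior(truth, tkf_sim, 0.4) + forward_loglik(
                    o, model3, 0.4)
                return joint - alignment_forward(side_a, side_b, model3, tkf_sim, 0.4)

            seq_only = true_post(sa.mask_tracks(x=False, ss=False),
                                 sb.mask_tracks(x=False, ss=False))
            seq_ang = true_post(sa.mask_tracks(ss=False), sb.mask_tracks(ss=False))
            if seq_ang > seq_only + 1e-12:
                wins += 1
            elif seq_ang < seq_only - 1e-12:
                losses += 1
            else:
                ties += 1
        # sign test: adding structure should win clearly more often than lose
        from scipy.stats import binomtest

        assert wins > losses
        p = binomtest(wins, wins + losses, alternative="greater").pvalue
        assert p < 0.01
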