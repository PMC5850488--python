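# Methods

## The model

`torusevo` implements a generative probabilistic model of the joint
evolution of protein sequence and local backbone structure in a pair of
homologous proteins (p_a, p_b) separated by an evolutionary time t_ab.
Local structure is represented per residue by the backbone dihedral-angle
pair (φ, ψ) — a point on the flat torus T² = [−π, π)² — together with a
3-class secondary-structure label (helix H, sheet S, coil C).

The model is an HMM along the aligned sites.  Each hidden node takes one of
h *evolutionary hidden states*; the transition matrix between neighboring
nodes captures local dependencies (helix-like states tend to follow
helix-like states).  A hidden state bundles two *site-classes* and a jump
process between them; a site-class specifies three conditionally
independent, time-reversible processes:

- **Amino acids**: a GTR-style CTMC Q_r = Λ_r · S · Π_r with a global 20×20
  symmetric exchangeability matrix S (190 free parameters), site-class
  equilibrium frequencies Π_r (19 free each) and rate scale Λ_r.  Rate
  variation across classes is carried by Λ_r; no global normalization of Q
  is imposed.
- **Secondary structure**: a 3-state CTMC R_r = V · Ω_r with a global
  symmetric V (3 free parameters) and class equilibrium Ω_r; the scale is
  absorbed into V since the processes share one time axis.
- **Dihedral angles**: a wrapped-normal (WN) diffusion on T², the torus
  analogue of the Ornstein–Uhlenbeck process, with stationary mean μ,
  drift parameters (α1, α2, α3) subject to α1·α2 > α3², and diffusion
  coefficients (σ1, σ2).  Its stationary law is the wrapped Gaussian
  WN(μ, ½A⁻¹Σ); its transition density is approximated by the standard
  multimodal pseudo-density: a mixture over windings m ∈ ℤ² of wrapped
  Gaussians with means μ + e^{−tA}(θ1 − μ + 2πm), covariance
  Γt = ∫₀ᵗ e^{−sA} Σ e^{−sAᵀ} ds, and weights given by the stationary
  Gaussian mass of each winding of θ1.  The pseudo-density collapses to a
  Dirac delta as t → 0 and to the stationary law as t → ∞, and satisfies
  the detailed-balance identity exactly, which the test suite checks to
  1e−8.

At a homologous site the site-class pair (ra, rb) is drawn from a two-state
jump chain with rate γ and equilibrium (π1, π2):

    p(ra | rb, t) = e^{−γt}·1[ra = rb] + π_{ra}(1 − e^{−γt}).

With ra = rb ("constant evolution") the three observation pairs are linked
by their time-dependent transition kernels; with ra ≠ rb (a "jump event")
both sides are drawn independently from their own class's stationary laws,
independently of t.  Jumps couple amino-acid exchanges directionally to
large conformational changes (e.g. a glycine exchange co-occurring with a
move to the left-handed-helix region).  The per-site likelihood is the
prior-weighted mixture over the four site-class pairs.

All component processes are reversible, so either protein may be treated
as the ancestor; the suite verifies that every likelihood is invariant
under swapping the two proteins.

**Missing data.** Each of the three factors is dropped when unobserved on
both sides and replaced by the observed side's stationary density when
observed on one side only; this follows from the conditional-independence
factorization and keeps partially observed data cheap.  At t = 0 exactly,
the continuous angle kernel is a Dirac delta; the likelihood engine uses
the delta-mass convention (unit transition mass on equality), so equal
pairs carry the ancestral stationary density and unequal pairs are
impossible.

## Statistical alignment

Insertions and deletions follow the TKF92 fragment model: fragments of
geometric length (extension probability r) are born at rate λ and die at
rate μ > λ.  The induced pair-HMM has Match/Delete/Insert states with the
classic TKF91 β/γ transition functions between fragments and a self-loop r
within fragments; r = 0 recovers TKF91 exactly (checked against an
independent implementation of the TKF91 formulas).  The alignment pair-HMM
is combined with the evolutionary HMM into one dynamic program over
(position in a, position in b, alignment state, hidden state), of
complexity O(|p_a|·|p_b|·h²).  Hidden-state transitions are applied between
consecutive emitted columns regardless of column type, and indel columns
emit the single-sided class-mixture of stationary densities — one
defensible reading of "neighboring dependencies amongst hidden states at
adjacent alignment sites"; whether hidden state should persist silently
through indel runs is a genuinely open design point.

The DP provides the marginal likelihood over all alignments, a MAP
alignment by the Viterbi recursion (joint over alignment and hidden path;
deterministic), and posterior alignment samples by stochastic backtrace.
Alignment accuracy is measured by a column-set similarity
2·|shared columns| / (m_pred + m_ref) (the reference metric's exact
formula was not available; only internal comparisons depend on this
choice) and by homology precision, the fraction of predicted homologous
site pairs present in the reference.

Default indel parameters: r = 0.5; λ/μ matched so that the expected
sequence length κ/(1−κ)·1/(1−r) equals the data's mean length, with
μ = 1 fixed.  All are exposed in `TKF92Params`.

## Training

Parameters are fitted by Stochastic EM.  The E-step draws exact posterior
samples of the latent variables: hidden paths by forward-filter
backward-sampling and one site-class pair per site from its conditional
posterior.  The M-step uses:

- count-based updates (with pseudocount 0.5) for amino-acid and
  secondary-structure equilibria, the HMM transition rows, and the class
  weights;
- bounded 1-D likelihood maximization for each Λ_r (on log scale, using the
  eigendecomposition of the unit-scale rate matrix so that P(Λt) is cheap)
  and a 2-D Nelder–Mead for each state's (π1, γ);
- Nelder–Mead over an unconstrained reparameterization of the six WN
  parameters per class (log α1, log α2, atanh-scaled α3, log σ1, log σ2,
  μ), on a subsample of at most 300 assigned observations, warm-started
  from the previous iteration (the mean from the circular mean of the
  assigned angles);
- a moment update of the global exchangeabilities: S_ij proportional to
  observed endpoint substitution counts over first-order expected
  opportunity, normalized to mean 1 off-diagonal (the scale is carried by
  Λ_r).  This estimator is rough at desk-scale data sizes; it can be
  disabled (`update_exchangeability=False`).

Per-pair evolutionary times t̂ are refreshed every few iterations by
bounded 1-D maximization on log t over [1e−4, 20] and quantized to two
decimals inside the WN M-step to keep the number of vectorized time groups
small.  The training objective (total fixed-alignment log-likelihood) is
tracked per iteration; StEM is not strictly monotone, but the trace is
reported and the suite checks that it improves.

**Initialization.** The 2h WN means and their pairing into states are
seeded from the data: pooled angles are clustered into 2h modes by k-means
on the (cos, sin) embedding in R⁴, and modes are paired greedily by their
normalized same-site co-occurrence across the two proteins — two modes
that appear on the two sides of the same homologous site are the signature
of a jump event and therefore belong to the same hidden state.  This
pairing signal is what makes the state structure identifiable at moderate
data sizes.  With multiple restarts, short probe fits run from different
seeds on a subset of pairs and the best probe objective continues on the
full data.

**Model selection** uses BIC = −2·logL + p·log n with n the number of
aligned site observation pairs and p from the deterministic parameter
counter (190 + 3 + 58h + h(h−1)).

## Synthetic study conditions

The package's generative sampler defines the study conditions; no external
corpus is required.  `example_model()` is a 3-state model emulating the
dominant Ramachandran regions: a right-handed α-helix state, a β-sheet
state, and a coil state whose minority site-class concentrates on glycine
with a left-handed-helix mode, so that jumps in the coil state couple a
glycine exchange to a large conformational change — the motif pattern the
jump mechanism is designed to express.  Amino-acid and secondary-structure
equilibria are biased toward the residues and labels typical of each
conformation; drifts α ≈ 2, diffusions σ ≈ 0.35–0.6 rad give realistic
within-basin spread; jump rates are 1.5/2/8 with class weights around
(0.7, 0.3); the sticky transition matrix (diagonal ≈ 0.8–0.9) produces
runs of like states.  The global exchangeability matrices are synthetic
(seeded random symmetric, mean-1 normalized): simulation requires a fixed
reversible process, not database-derived rates, and no claim about real
amino-acid exchangeabilities depends on them.

What the generator does *not* emulate: experimental noise in dihedral
angles (at t = 0 simulated pairs are exactly identical, unlike real
redundant structures), global/tertiary constraints (compactness, contact
networks), length variation of real families beyond the TKF92 prior, and
database-derived exchangeabilities.  Passing tests therefore demonstrate
internal correctness and recoverability under the model's own assumptions,
not performance on real structural corpora.

Desk-scale problem sizes used by the validation suite (chosen once as the
package's study conditions): parameter recovery refits 200 pairs × 150
sites; model selection runs 10 replicates of 25 pairs × 60 sites over
h ∈ {1, 2, 3, 4, 6}; time-estimation consistency uses 30 pairs of length
250 across t ∈ [0.05, 1.0]; prediction benchmarks use 20 pairs of length
60 with 5 posterior samples per combination.

## Numerical choices

- Winding truncation K = 1 (3×3 windings) for likelihood evaluation, K = 2
  in unit tests and quadrature checks; at concentrations typical of
  backbone data K = 1 is accurate to well below test tolerances, and the
  diffuse illustration parameters (σ = 1.5) need K = 2.
- Γt in closed form, Γt = Γ∞ − e^{−tA} Γ∞ e^{−tAᵀ} with Γ∞ = ½A⁻¹Σ, via an
  overflow-safe closed-form 2×2 matrix exponential (the drift matrices
  here always have real eigenvalues).
- CTMC matrix exponentials by eigendecomposition of the symmetrized rate
  matrix (exact for reversible chains); P(0) returns the exact identity;
  a scaling-and-squaring fallback is provided for arbitrary rate matrices.
- Forward/backward recursions in log space; posteriors renormalized per
  site.
- All samplers take an explicit seed or `numpy.random.Generator`; there is
  no hidden global state.
- Half-open interval convention [−π, π); π wraps to −π.

## Known limitations

- The pseudo-transition density is an approximation; Chapman–Kolmogorov
  holds only approximately (the suite reports the defect rather than
  asserting a hard bound).
- The StEM M-step is approximate (hard assignments, subsampled WN
  objectives, moment update for S); fitted likelihoods on small data sets
  can sit below the generating model's, which is why initialization
  carries the identification burden.
- Only pairs (two taxa) are supported; site-classes do not evolve along a
  tree — the jump construction abstracts the end-points of that process.
- Exactly two site-classes per hidden state are supported.
- 3-class secondary structure is consumed as labels (8-class input is
  reduced by H,G,I→H; E,B→S; else→C); no assignment from coordinates.
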