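# Methods

This package reconstructs families of stochastic differential equations
from ensembles of noisy trajectories recorded across a heterogeneous cell
population, and ships the three ground-truth generators used to study the
method: a damped-oscillator circadian SDE, an exact lattice simulator of
RPA–ssDNA binding, and a noisy NFκB signaling core.

## Model

Cell-to-cell heterogeneity ("extrinsic noise") is represented by a
parameter vector ω; within a stratum of fixed ω, a cell's state follows

    dX = f(X; ω) dt + σ(X; ω) dB_t,

whose Wiener term models the intrinsic reaction noise.  Drift f and
diffusion σ are unknown; each is represented by a multilayer perceptron
that takes (X, ω) concatenated as input, so a single fitted model covers
the whole family of SDEs indexed by ω.

### Loss

Trajectory ensembles are compared through a *temporally decoupled* squared
Wasserstein-2 distance: at each observation time t_j, the empirical
marginal of the simulated ensemble is compared with the observed marginal,
and the per-time squared W2 values are integrated over the horizon with a
left-Riemann rule (weights Δt_j, so non-uniform grids are supported).  The
training objective sums this quantity over the strata ω ∈ Λ of the
training grid:

    L(Λ) = Σ_ω ∫_0^T W2²(μ_ω(t), μ̂_ω(t)) dt .

Marginals are compared one state component at a time and summed over
components.  For one-dimensional empirical measures with equal counts the
squared W2 has a closed form — the mean squared difference of order
statistics — which is exact, cheap and differentiable almost everywhere.
The dimension decoupling is a deliberate surrogate for the exact
d-dimensional empirical W2 (an assignment problem, non-smooth and
expensive to differentiate); it is exact for d = 1, and the exhaustive
assignment value is retained as a small-n test oracle.  The per-component
sums (rather than means) fix the constant factor.  Identifiability
consequences of the decoupling are discussed under *Limitations*.

### Training

Fitting follows simulation-based gradient descent: each epoch simulates
predicted ensembles from the observed initial states with Euler–Maruyama
(fresh Wiener increments per epoch), evaluates L(Λ), and backpropagates
through the entire integration unroll (the gradient of the 1-D W2 with
respect to a predicted sample is 2(b_k − a_match(k))/n at the
order-statistics coupling, with ties broken by stable sort so gradients
are deterministic).  The networks, the reverse-mode pass, and the Adam
optimizer are implemented in numpy inside the package; the reverse pass
needs the per-step activations of both networks, which for the problem
sizes used here fit comfortably in memory.

Defaults (all overridable through `RunConfig`): two hidden layers of
width 48 with tanh activations for both networks; output layers scaled at
initialization (0.1 for drift, 0.05 for diffusion) so the initial field is
close to zero and the first simulations cannot blow up; Adam with learning
rate 10⁻³–3·10⁻³ and an optional cosine decay; global gradient-norm
clipping at 50; optional decoupled weight decay; optional exponential
moving averaging of the weights (`ema_decay`), which suppresses the
fit's chasing of the per-epoch stochastic-gradient noise and markedly
stabilizes the recovered drift field — the averaging window should stay
shorter than the slow growth phase of the diffusion amplitudes; optional
`n_pred_factor` k that seeds k predicted trajectories per observed one
(observed samples are duplicated k-fold, which leaves the empirical
measure and hence the loss scale unchanged while reducing gradient
noise).  The diffusion output is an unconstrained d×m matrix: σ is
identifiable only through σσᵀ, so no sign or shape constraint is imposed,
and all evaluation goes through σσᵀ.  The Wiener dimension m equals the
generator's dimension where known (2 for the circadian and NFκB systems),
else m = d.

All randomness flows from one seed through named substreams
(`data.substream`): dataset simulation, weight initialization, per-epoch
training noise, prediction, subsampling.  Fits are bit-reproducible for a
fixed seed and platform.

### Latent components

For partially observed systems (NFκB: 52 state components, two observed),
the field evolves the full state but the loss touches only the components
in `latent_mask`.  Everything else is unchanged; the unobserved components
act as latent dynamics shaping the observed ones.

## Evaluation metrics

*Relative drift error*: mean over trajectories of
(Σ_j |f − f̂|₁) / (Σ_j |f|₁) along each trajectory, both fields evaluated
at the observed states (teacher-forced).  The printed source formula sums
over trajectories outside the ratio while its denominator carries no
trajectory index; read literally the quantity would grow with the number
of trajectories, so the per-trajectory-ratio mean is used — the only
reading consistent with the reported O(0.1) magnitudes.  *Relative
diffusion error* is the analogous ratio for σσᵀ in the entrywise-absolute
matrix norm, which makes it invariant to right-orthogonal refactoring and
to the sign of σ̂.  Trajectories with an identically zero denominator are
excluded with a warning.

## Ground-truth generators

### Circadian damped oscillator

x (per mRNA) and y (per protein) follow the linear rotation–damping drift
(−αx − βy, βx − αy) with α = 0.19, β = 0.21; the origin is a stable
spiral, so sustained single-cell rhythms are noise-induced.  Four
diffusion forms: constant σ₀[[1,c],[c,1]]; Langevin σ₀[[|x|,c|y|],[c|x|,|y|]];
linear σ₀[[x,c|y|],[c|x|,y]] (the signed diagonal is implemented exactly
as printed — the sign asymmetry is part of the model); and a diagonal
multiplicative form with per-cell coefficients, diag((σ₀+σ₁k₁)x,
(σ₀+σ₁k₂)y).  The study grid takes 25 combinations (σ₀, c) ∈
{0.10, …, 0.30} × {0.2, …, 1.0}, 50 trajectories each, t ∈ [0, 1] from
x₀ = (0, 1).  The integration step is Δt = 0.02 (50 steps): halving it
changes the study-scale losses by well under 5%.  Stationary covariance
on fixtures is checked against the 2×2 Lyapunov-equation solution.

### RPA–ssDNA lattice binding

An exact continuous-time Markov chain on disjoint-footprint configurations
of a length-L lattice: 20-nt-mode binding at rate k₁ *per eligible start
position* (so free RPA is an unlimited reservoir; an eligible start needs
20 consecutive free sites), unbinding at k₋₁, extension into the 10 nt
immediately downstream (30-nt mode) at k₂, reversion at k₋₂.  Footprints
are 0-based half-open intervals; the extension direction is fixed
downstream.  Defaults: L = 5000 nt, horizon 5000 s, 51 output points;
k₁ = 10⁻³, k₋₁ = k₋₂ = 10⁻⁶ s⁻¹, k₂ swept over lg k₂ ∈ {−4.0, …, −1.5}
(26 values, 100 trajectories each, 50/50 train/test).  The simulator is a
direct Gillespie implementation (propensities recomputed from the
configuration each event) with a numba-jitted core and an identical
pure-python fallback; outputs are the filling fractions x₁ = 20N₂₀/L,
x₂ = 30N₃₀/L sampled by last-value interpolation.  For the surrogate and
its losses the time axis is normalised to units of the horizon, which puts
the sweep's W2 losses on the same scale as the other systems.  The
irreversible limit is validated against an independent brute-force random
sequential adsorption oracle, and the single-site binding time against its
exponential law.

### NFκB core

The three noisy components follow the printed stochastic equations for
IκBα mRNA (u₆: basal + Hill-activated transcription by u₅₂, first-order
decay, +σ₁dB₁), cytoplasmic NFκB (u₉) and nuclear NFκB (u₁₀), the latter
two exchanging through import/export with volume ratio v and sharing one
Wiener increment with opposite signs (±σ₂dB₂), so translocation noise
moves NFκB between compartments without creating it — the noise
contribution to d(u₉+u₁₀) cancels identically, which is asserted in the
tests.  The remaining 49 components evolve deterministically under a
pluggable right-hand side whose parameters come from configuration files;
the bundled `SyntheticLatentRHS` is a deliberately small synthetic
stand-in — a single negative-feedback loop (u₁₀ → u₅₂ → u₆ → IκBα →
nuclear complex → export) with all other components inert — chosen to
give a stable, oscillatory representative cell with an hour-scale
period.  Its rate constants keep the IκBα mRNA pool small (fast mRNA
turnover, high translation gain) so that *both* printed noise channels
are observable in the u₅+u₁₀ readout: across the default noise grid each
axis changes the readout dispersion by roughly a factor of two, matching
the qualitative behaviour of the system it emulates.  It is not the
published 52-dimensional network, whose kinetic constants are consumed
from config when available, and nothing in the package depends on its
specific form beyond stability and this observability property.

Concentrations are reflected at zero after each Euler step (count
recorded in metadata).  The 5-minute output frames are far coarser than
the stability limit of the fastest reactions, so each frame interval is
integrated with 25 internal substeps by default.  The noise grid spans
lg σ₁ ∈ [−3.2, −2.2] × lg σ₂ ∈ [−2.5, −1.5], 11 values per axis (121
combinations), anchored at the two documented example corners.  The
experimental-trajectory emulator produces scalar u₅+u₁₀ readouts on 31
frames at 5-minute spacing from a mixture over noise levels, with the
per-cell ground truth stored only in metadata (real recordings carry no
labels).  One printed sign in the u₉ equation (the +k_imp u₉ import term)
reads as a source rather than a sink; it is implemented exactly as
printed, and the default rate constants keep the net u₉ balance negative
so the representative cell remains stable.

## Baselines

All comparators expose the neural SDE's `predict(x0, omega, times,
n_traj, seed)` contract and are scored by the *same* extrinsic-noise W2
code — there is no per-family metric path.  RNN (tanh, hidden 64) and
LSTM (hidden 32) are teacher-forced next-increment predictors rolled out
autoregressively; widths match the SDE's parameter count within 2×.
Their rollouts are deterministic, so against stochastic test data their
per-time W2 is bounded below by the ensemble variance (asserted on
fixtures).  The neural ODE reuses the SDE trainer with the diffusion
frozen at zero.  The Gaussian-process baseline fits one scikit-learn
`GaussianProcessRegressor` (constant × RBF + white noise) per (time,
component) over ω, with hyperparameters optimized at anchor times and
reused in between; prediction "ensembles" are i.i.d. posterior-predictive
draws, so the white-noise level reproduces the trajectory dispersion
under a homoscedastic-in-ω assumption.

## Noise-intensity inference

Scalar-readout trajectories are ranked by cosine similarity to the
deterministic representative-cell trajectory and cut into contiguous
groups of size g (the workflow's stated assumptions — shared drift across
cells, shared noise intensities within a group — are encoded here).  A
regression MLP maps a group to (lg σ₁, lg σ₂).  The default features are
permutation-invariant summary channels: per-time mean and standard
deviation across members, a per-interval roughness channel (the member
mean absolute increment, which carries the Brownian intensity even for
g = 1), and the mean member similarity.  An alternative featurization
that additionally concatenates the members sorted by similarity is
available (`feature_mode="concat"`), but it memorizes group composition
and generalizes badly for g beyond a few at realistic corpus sizes, so
the summary features are the default.  Feature standardization is folded
into the first layer after training so checkpoints are self-contained.  Estimates are
exponentiated to the linear scale, and relative error is the mean
componentwise |σ̂−σ|/σ on the linear scale (the published error values
are dimensionless ratios; a log-scale alternative would change only the
reporting).  Inferred intensities can then drive the fitted neural SDE to
reconstruct each group, scored by the same temporally decoupled W2.

## Problem sizes used by the shipped runs

The acceptance script trains the circadian model on the full printed grid
(25 strata × 50 trajectories) for 800 epochs with the split weight
averaging (constant form) or 500 epochs plain (Langevin, linear, whose
multiplicative noise makes the long averaging window counterproductive)
— single-CPU desk-scale budgets chosen so the three fits complete in
minutes; the RPA sweep runs all 26 k₂ values at
100 SSA trajectories each with the GP baseline scored on the 50-trajectory
test halves.  The test suite uses reduced problem sizes with
correspondingly looser bounds: the comparator ranking runs a 6-point k₂
sweep (END-nSDE trained for 5000 epochs at learning rate 3·10⁻², the
budget at which its test loss drops below the GP's sampling-floor
excess); the noise-grid generalization check trains on two noise levels
and evaluates a held-out intermediate one; and the group-size study
scales the labelled corpus with g (8 groups per noise level at every g)
so each regressor sees a comparable number of training groups.

## Known limitations

- The dimension-decoupled loss sees only per-component marginals, so the
  cross-component diffusion correlation is identified solely through the
  slow rotation coupling of the drift (β = 0.21 over a unit horizon);
  reconstructed off-diagonal diffusion structure is systematically the
  least-constrained part of the fit, and diffusion errors are larger than
  drift errors for correlated noise forms.
- Drift estimates are most reliable inside the state-space tube visited
  by the data; extrapolation off-tube is regularized only by network
  smoothness.
- Deterministic recurrent baselines are intentionally standard; their
  scores reflect the family's inability to carry dispersion, not tuning
  effort.
- The synthetic NFκB latent stand-in reproduces qualitative features
  (stable damped oscillation, bounded concentrations) but no quantitative
  property of the published network; conclusions from tests that use it
  transfer to the real system only at the level of the workflow.
- The GP baseline assumes dispersion constant in ω at fixed time; under
  strongly ω-dependent dispersion its draws are over- or under-dispersed
  at the extremes.
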