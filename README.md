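# endnsde

Reconstruction of stochastic differential equations from noisy trajectory
ensembles measured across a **heterogeneous cell population** — neural
drift and diffusion fields conditioned on the extrinsic parameters that
vary from cell to cell, trained with a temporally decoupled Wasserstein-2
loss.

Gene-regulatory dynamics are doubly noisy: intrinsic reaction
stochasticity makes single-cell trajectories fluctuate, and extrinsic
heterogeneity (cell state, enzyme abundances, noise intensities) makes
different cells follow *different* stochastic laws.  This package targets
researchers in quantitative cell biology who want a differentiable
surrogate for such dynamics.  For a parameter vector ω describing a
stratum of the population, the state follows

    dX = f(X; ω) dt + σ(X; ω) dB_t ,

and both f and σ are represented by neural networks taking (X, ω) as
input, so one fitted model covers the whole family of SDEs.  Training
minimizes the extrinsic-noise-driven, temporally decoupled squared W2
loss

    L(Λ) = Σ_{ω∈Λ} ∫₀ᵀ W2²( μ_ω(t), μ̂_ω(t) ) dt ,

where μ_ω(t) is the observed single-time marginal in stratum ω and
μ̂_ω(t) the marginal simulated from the model (Euler–Maruyama from the
observed initial states).  Per-time 1-D marginals make the loss exact,
cheap (order statistics) and differentiable; the gradient is
backpropagated through the entire integration unroll.  Networks,
optimizer and reverse-mode pass are implemented in numpy inside the
package — there is no deep-learning framework dependency.

The package also ships the three ground-truth generators used to study
the method (a damped-oscillator circadian SDE, an exact Gillespie
simulator of two-mode RPA binding on an ssDNA lattice, and a noisy NFκB
signaling core with pluggable latent dynamics), the evaluation metrics
(relative drift/diffusion errors through σσᵀ, per-stratum W2 maps),
RNN / LSTM / neural-ODE / Gaussian-process comparators scored by the same
loss, and a cosine-similarity noise-intensity inference workflow.
See `docs/methods.md` for the scientific details and design choices.

## Worked example

Recover a family of circadian SDEs across the 25-point (σ₀, c) noise
grid, then check the reconstruction against the generator:

```python
import numpy as np
from endnsde import EndNSDE, RunConfig
from endnsde import circadian as circ
from endnsde.metrics import drift_error
from endnsde.wasserstein import extrinsic_loss

grid = circ.make_grid_dataset("const", seed=11)   # 25 strata x 50 trajectories
cfg = RunConfig(seed=7, imax=300, hidden=(48, 48), lr=3e-3,
                lr_schedule="cosine", weight_decay=1e-4)
res = EndNSDE(grid, cfg).fit()
print(res.summary())

true = circ.field_for_form("const")
de = np.mean([drift_error(true, res.field, e.ensemble) for e in grid.entries])
pred = res.predict_grid(grid, seed=123)
w2 = np.mean(list(extrinsic_loss(grid, pred).per_omega.values()))
print(f"mean relative drift error {de:.3f}, mean W2 loss {w2:.4f}")
```

Output:

```
Extrinsic-noise-driven neural SDE — fit summary
================================================
state dim:        2
param dim:        2
noise dim:        2
hidden layers:    (48, 48)
epochs run:       300 (imax 300)
learning rate:    0.003
seed:             7
initial W2 loss:  2.053691
final W2 loss:    0.142312
training strata:  25 omega values
mean relative drift error 0.204, mean W2 loss 0.0053
```

The initial loss is the W2 distance between the data and the untrained
(near-zero) field; after 300 epochs the simulated ensembles are, on
average per stratum, within 0.006 squared W2 of the data, and the learned
drift agrees with the generator's rotation–damping field to ~20% in
relative l1 norm along the observed trajectories (longer budgets with
weight averaging tighten this to ~0.14; the acceptance script uses 800
epochs).

The same objects drive the other systems, e.g.
`rpa.make_k2_dataset()` for the 26-point conversion-rate sweep of the
lattice binding model, and `endnsde simulate / train / evaluate /
benchmark / infer-noise` on the command line for file-based runs (every
run writes a JSON manifest with its resolved options and seeds).

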