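# Methods

## The model

`flownode` infers low-dimensional latent dynamics from binned spike counts
with a sequential autoencoder.  The observation model is

    z_{t+1} = z_t + f(z_t)          latent dynamics, z in R^D
    y_t     = exp(g(z_t))           firing rates of N neurons (spikes/bin)
    x_t     ~ Poisson(y_t)          observed counts

and the estimator mirrors it:

* **Encoder** — a bidirectional GRU consumes the spike window x_{1:T}; the
  final forward/backward hidden states are concatenated into h_T.
* **Initial condition** — phi(h_T).  For linear/MLP readouts phi is affine
  into R^Dhat.  For the flow readout phi is affine into R^N followed by the
  flow's reverse pass (so the initial condition lives in the space the
  readout can invert), trimmed to the first Dhat coordinates.
* **Generator** — a Neural ODE: zhat_{t+1} = zhat_t + alpha * MLP(zhat_t),
  unrolled with Euler steps of one bin (alpha = 0.1 stabilizes early
  training; the final MLP layer is zero-initialized so the dynamics start
  near the identity).  The unroll emits zhat_1..zhat_T, with zhat_1 one step
  from zhat_0, so the output window length matches the input.
* **Readout** — g maps each latent state to log-rates.  Three variants:
  a single affine layer (`linear`); an MLP with two ReLU hidden layers
  (`mlp`); or the approximately injective residual flow (`flow`):
  zero-pad z to R^N, apply K = 20 additive refinements
  u <- u + beta * MLP(u) with beta = 0.1 and one shared MLP, and exponentiate.
  The reverse pass serially subtracts the same MLP and trims the padding;
  because the subtraction is evaluated at the current state, the round trip
  is the identity only to O((beta L)^2) per step (L = Lipschitz constant of
  the MLP), and the map is injective whenever beta * L < 1.
  `flow.lipschitz_estimate` reports a finite-difference lower bound and a
  spectral-norm-product upper bound on beta * L.

Training minimizes the Poisson negative log-likelihood
mean(lambda - x log lambda) with Adam (the constant log x! term is dropped
from the objective; reported Spike NLL includes it).  Gradients flow through
the full unroll (ordinary backpropagation through time).  The stack runs on
a small reverse-mode autodiff engine written for this package
(`flownode.autodiff`); the GRU recurrence is a single fused graph node with
a hand-derived backward pass, verified against finite differences in the
test suite.

## Synthetic benchmark

The generator emulates a low-dimensional chaotic system observed through
noisy spiking:

* **Latent system** — the Arneodo-Coullet system
  x' = y, y' = z, z' = -a x - b y - c z + d x^3 with
  (a, b, c, d) = (-5.8, 3.8, 1.0, -1.0).  This coefficient set is chaotic
  (largest Lyapunov exponent ~0.15 per time unit) and, unlike nearby values
  such as b = 3.5 which only exhibit transient chaos, stays bounded over at
  least 1.4e4 time units.  It has three fixed points, at x = 0 and
  x = +/-sqrt(a/d) (y = z = 0), with analytic Jacobians — the oracle used by
  the fixed-point tests.
* **Integration** — fixed-step RK4 with 10 substeps per bin and a 1000-bin
  burn-in.  Substepping makes the one-bin discrete map agree with the matrix
  exponential of the continuous Jacobian to ~1e-9 at the fixed points, and
  keeps ground-truth trajectories free of the Euler discretization error the
  model itself incurs.  Trial initial conditions are seeded random phases
  along a single burned-in reference orbit (spaced >= 100 bins so chaos
  decorrelates them); unlike independent box draws, orbit phases can never
  escape the basin of attraction.
* **Bin width** — dt = 0.07 time units, so a 70-bin segment spans ~1.5
  periods of the attractor's dominant oscillation (period ~3.3).
* **Embedding** — each neuron's activation is the projection of z onto a
  random encoding vector with entries ~ U[-0.5, 0.5], standardized to zero
  mean/unit variance over the dataset, then warped by a scaled sigmoid
  rate_scale * sigmoid(s_i a_i) with the N scales s_i log-spaced over
  [10^0.2, 10] — from quasi-linear to nearly step-like.  The
  `lin_exp`/`linear` alternative makes log-rates affine in the activations
  (exactly representable by a linear readout), used for the effective-rank
  experiment.  Standardization statistics are stored so the true activation
  curve of each neuron can be reconstructed for embedding-recovery metrics.
* **Rates and spikes** — rate_scale = 1.0 spikes/bin at the sigmoid ceiling
  gives ~0.5 spikes/bin on average, at the upper end of typical cortical
  values for short bins; counts are independent Poisson draws per
  bin/neuron/trial.  Split: 80/20 at the trial level.

What the generator does **not** emulate: external inputs to the latent
system, non-Poisson count statistics (refractoriness, bursting), slow
nonstationarities, and electrode-level noise.  Passing tests therefore show
recovery under the model's own observation assumptions, not robustness to
real-data artifacts.

## Metrics

* **Spike NLL** — mean per bin-neuron Poisson NLL, log x! included.
* **Rate R2** — per-neuron R2 between inferred and true rates over all
  validation bins, averaged (zero-variance neurons excluded with a warning).
* **State R2** — R2 of one multioutput affine regression from true to
  inferred latents on all flattened timepoints, variance-weighted across
  output dimensions (the standard multioutput convention; per-dimension
  uniform weighting gives nearly identical values here).  The fitted map is
  reused to carry fixed points and encoding vectors into the model's latent
  space.  A low-dimensional projection of the truth can score high — State
  R2 is read together with reconstruction metrics.
* **Effective rank** — exp of the entropy of the nuclear-norm-normalized
  singular values of a linear readout's weight matrix.
* **Cycle consistency** — a probe MLP (two 64-unit hidden layers,
  scikit-learn, 80/20 split, seeded) predicts inferred latents from
  predicted log-rates corrupted with Gaussian noise of standard deviation
  sigma in {0, 0.1, 0.25, 0.5, 1.0}; the held-out R2 per sigma measures how
  much latent variance is actually expressed in the rates.
* **Activation recovery** — encoding vectors are carried through the linear
  part of the State-R2 map (directions, so no offset), inferred latents are
  projected onto them, and the implied (activation, rate) curve is compared
  to the true curve after a least-squares affine calibration of the
  activation axis (Nelder-Mead over scale/offset with multiple starts, since
  the model's activation units are arbitrary).
* **co-bps** — (NLL_null - NLL_model) / (total spikes * log 2) with
  per-neuron mean-rate nulls.  Only the formula is implemented; the
  held-out-neuron protocol for biological data is out of scope.

## Fixed-point analysis

Candidates start from 256 points sampled from the inferred validation
latents (plus 5% jitter) and BFGS-minimize q(z) = 0.5 ||f(z)||^2 with the
analytic gradient J^T f; converged points with q < 1e-6 are deduplicated
within 1% of the latent range.  Each fixed point is characterized by the
Jacobian of the update map I + df/dz — computed either by central finite
differences or autodiff (both provided; they agree to 1e-5 in tests) — and
classified against the unit circle (attractor / repeller / saddle /
spiral-in / spiral-out / center-like, with non-real eigenvalues marking
rotation).  Ground-truth comparisons transform the true fixed points
through the State-R2 affine map, greedy-match by distance, and report
per-pair location errors and Hausdorff distances between eigenvalue sets.

## Problem sizes and training configuration

The full-scale conditions are 1175 trials of 70 bins and 12 neurons.  The
flow model evaluated at the true dimensionality runs on that default trial
count with a ~90-epoch budget (a few minutes on one core); the remaining
comparisons run a desk-scale configuration chosen to keep the complete
suite in minutes: 400 generated trials
(320 train / 80 validation), encoder hidden size 64, NODE MLP (64, 64) with
tanh, readout MLPs (64, 64), Adam at 5e-3 with minibatches of 64, stepwise
lr decay, global gradient-norm clipping at 200, and several hundred epochs;
float32 parameters.  Decoupled weight decay (global and NODE-specific) is
available on the config and off by default.  Training is
deterministic given the config seed and backend thread count.  Hidden
sizes, epoch counts, optimizer settings and trial counts are configurable;
none of the qualitative comparisons below depend on these choices.

At this spike-count SNR (~0.5 spikes/bin) the Poisson likelihood ceiling is
close: the acceptance script reports the Spike NLL of the *true* generating
rates and of the per-neuron mean-rate baseline alongside each model's NLL,
and trained models land within a few hundredths of a nat per bin of the
true-rate value — residual rate error reflects information limits of the
counts as much as model error.

## Design choices where the design was open

* Time alignment: the unroll emits z_1..z_T (z_0 is not emitted), keeping
  input and output windows the same length.
* The flow's reverse pass is the literal serial subtraction (not an iterated
  fixed-point solve, not spectral normalization); forward and reverse share
  one MLP, which is what makes the reverse an approximate inverse.
* Padding order: latent coordinates first, zeros last; the reverse trims the
  first Dhat coordinates.
* Poisson NLL uses rates in spikes/bin with no exposure term.
* No dropout or weight decay by default (regularization hooks exist on the
  config); hyperparameter search infrastructure is out of scope.
* The `zero` test system (f = 0) exists purely to exercise degenerate paths.

## Known limitations

* Autonomous dynamics only — no inferred inputs; activity driven by
  unmodeled inputs will be absorbed into initial conditions or dynamics.
* The flow is approximately injective; the spectral-norm certificate is
  reported, not enforced.
* Recovery quality degrades with lower firing rates.
* Latent-chart identifiability: the Poisson likelihood is invariant under
  any invertible reparameterization of the latent space (the readout can
  absorb the inverse warp), so nothing in the objective itself prefers the
  affine chart that State R2 rewards.  In this implementation, flow- and
  MLP-readout models trained at desk scale reliably recover the rates but
  settle into a nonlinearly warped chart: State R2 plateaus far below Rate
  R2, and training longer deepens rather than unwinds the warp.  A linear
  readout on linearly embedded data — where the readout anchors the chart —
  aligns well, confirming the effect is chart selection, not estimation.
  Whatever implicit bias produces near-affine charts in the original
  GPU-scale training regime is not reproduced by the desk-scale schedule
  used here; the acceptance test for latent recovery documents the gap.
* Biological-data ingestion (the co-smoothing held-out-neuron protocol,
  behavioral decoding) is out of scope; only the co-bps formula ships.
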