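# Methods

`ctdbench` is a self-contained benchmark for *data-driven latent
dynamics models* of neural population spiking.  Everything is simulated:
a task environment defines an input→output computation, a recurrent
network trained on that task supplies ground-truth latent dynamics, a
calibrated linear-exponential embedding turns its hidden trajectories
into Poisson spike counts, and candidate models are scored on how well
they recover rates, latent state, external inputs, and dynamical
structure from those spikes.  This note documents the model choices,
parameters, and numerical decisions, and what the synthetic setting
does and does not establish about real neural data.

## Task environments

**Flip-flop (1- or 3-bit).**  Each of `n_bits` channels emits one-step
pulses of amplitude ±1 at Bernoulli(0.02)-per-step times; the target on
each channel is the sign of the most recent pulse.  Gaussian noise
(sd 0.05) is added to inputs only — targets are computed from the clean
pulse train, so input noise can never corrupt the supervision signal.
A forced pulse at t=0 sets the initial bit, making the target defined
from the first step.  Overlapping pulses simply overwrite the sign.
The 3-bit version has 8 discrete memory states; a system solving it
must be multistable.

**Memory Pro/Anti.**  A two-task delayed-response environment: 7 input
channels (2 one-hot task cue, 4 sensory of which 2 carry
(cos θ, sin θ) during the stimulus phase, 1 fixation) and 3 outputs
(fixation echo, x, y).  Phases run fixation → stimulus → memory →
response with default lengths 20/40/60/40 steps.  MemoryPro reports the
stored angle during the response phase; MemoryAnti reports θ+π.  These
lengths are free parameters of the environment — only the phase
ordering and response rules are constrained by the task definition.

Time is abstract steps; a nominal bin width `dt = 0.01 s` is carried as
metadata solely to express firing rates in spikes/s.

The task loss is the mean squared error between outputs and targets
(optionally up-weighting response-phase steps for the memory tasks).
All generation is a pure function of `(config, seed, n_trials)`.

## Task-trained (ground-truth) models

A TT model is a discrete-time system `z_{t+1} = f(z_t, u_t)` with affine
readout.  Three architectures: a GRU (the workhorse), a linear system
(deliberately incapable of multistability — the underfitting
reference), and a neural ODE (MLP vector field, fixed-step RK4, one
step per bin).  Parameters are initialized uniform with fan-in scaling;
hidden state starts at zero.

Training draws fresh trials every iteration (an infinite-data regime),
uses Adam with gradient-norm clipping at 1.0, and stops when a
validation task score reaches a criterion.  The score for flip-flop is
the fraction of (trial, step, channel) entries whose output sign
matches the target.  Defaults: hidden size 64 (flip-flop) / 128
(memory), learning rate 3e-3 (chosen over 1e-3 for ~2× faster
convergence at equal stability on the numpy backend), batch 64,
criterion 0.95.

The *canonical* 3BFF network used by the experiment harness trains to a
stricter criterion of 0.999.  This matters for fixed-point structure:
at a score near 0.98 the 8 attractors have not fully crystallized —
about half of the memory states are still slow manifolds rather than
exact fixed points, and the fixed-point census is unstable.  By 0.999
all 8 states are isolated attractors (typically reached in 200–400
iterations).

## Spiking simulation

`N` of the `D` hidden dimensions are sampled without replacement; each
neuron's rate is `exp(gain · z_sel + offset)` (spikes/s) scaled by `dt`
to spikes/bin and used as a Poisson rate, one count bin per simulation
step.  Gains have random sign and magnitudes scaled by the inverse
standard deviation of the selected dimension; offsets are calibrated on
the latent batch so every neuron's mean rate equals the target
(default 10 spikes/s).  Rates are capped at 100 spikes/s, and gains are
iteratively shrunk until the 99.9th-percentile rate sits below 90% of
that cap — without this, unbounded latents (e.g. from linear systems)
produce rate distributions dominated by clipped excursions that carry
most of the variance but little information, which corrupts
variance-weighted scores.  All gains are nonzero and dimensions
distinct, so the true embedding is injective: any structure a DD model
infers beyond the latents is its own invention, not a simulator
null space.

Defaults: N=40 neurons from a D=64 network, 25% of neurons held out,
80/20 train/valid trial split.  Datasets serialize to HDF5
(`data/{z,n,y,u}`, `masks/{heldin,trial_split}`, provenance attrs,
format version) with a JSON manifest sidecar.

## Data-driven models

All DD baselines are sequential autoencoders sharing one skeleton: a
bidirectional GRU encoder reads *held-in* spikes into a Gaussian
posterior over the initial latent state; a latent dynamics model rolls
forward; an affine-exponential readout predicts rates for *all*
neurons.  The training loss is the all-neuron Poisson negative
log-likelihood (held-in readout path, standard co-smoothing
convention) plus KL terms.

The initial condition is variational for *every* architecture, not just
the input-inferring one.  With a deterministic encoder the IC path
overfits single-trial spike noise: validation NLL stays flat while rate
and state recovery degrade with continued training, because NLL is
nearly blind to rate errors that R²-type metrics punish.  The unit
Gaussian KL on the IC, together with Bernoulli dropout (p=0.25) on the
encoder's spike inputs, closes that channel; both are standard in this
model family.  With them, a linear autoencoder trained on data from a
linear ground-truth system recovers rates and latent geometry almost
exactly (rate R² ≈ 0.95, state R² ≈ 0.99 at desk scale).

Dynamics variants: affine (`linear-sae`), GRU (`recurrent-sae`),
RK4-integrated MLP vector field (`node-sae`), and the input-inferring
`input-infer-sae`.  The latter adds a second bidirectional encoder
whose per-step features, concatenated with the current generator
state, feed an MLP controller that outputs a Gaussian posterior over
the inferred input û_t; a GRU generator consumes û samples.  The û
posterior is penalized by a Monte-Carlo estimate (one reparameterized
sample per step) of its KL divergence to a Student-t prior
(df=5, scale 1) — no closed form exists for Gaussian‖Student-t.  The
prior's heavy tails and sharp mode promote sparse inferred inputs; the
penalty weight is the experiment's central knob.

Training: Adam (lr 5e-3, 0.999/epoch decay, clip 5.0), batch 64, early
stopping on validation NLL with parameter restore; a non-finite loss
aborts with the last good checkpoint.  Readout biases initialize at
each neuron's mean log spike count.  Inference is deterministic
(posterior means).

## Metrics

All R²-type metrics are variance-weighted means of per-dimension
coefficients of determination; zero-variance dimensions are excluded.
Affine fits use least squares with a trace-scaled ridge (1e-8) purely
for conditioning, intercept always included.

* **Rate R²** — predicted vs. true rates, weighted by true-rate
  variance (reconstruction, needs ground truth).
* **State R²** — affine fit *from* true latents *to* inferred latents,
  scored in inferred space with inferred-variance weights.  Direction
  is deliberate: variance the true system cannot explain (invented
  features) lowers the score; true features the model missed do not.
* **Input R²** — affine fit *from* inferred inputs *to* true inputs,
  scored in true-input space (the mirrored direction).
* **co-BPS** — Poisson log-likelihood ratio of held-out spikes under
  predicted rates vs. each neuron's mean rate over the evaluation set,
  divided by total spike count and ln 2: bits per spike.  Exactly 0
  for the mean-rate predictor.
* **Cycle-consistency** — PCA-rotate inferred latents and inferred
  log-rates, fit a linear map latents→log-rates, zero singular values
  carrying <1% of total squared-singular-value mass, regenerate the
  latents through the pseudo-inverse, and compute the
  variance-weighted R² between inferred and regenerated latents.
  Latent dimensions in the (thresholded) null space of the inferred
  embedding cannot be regenerated, so invented features lower the
  score without any ground truth.  Note the score is exactly 1 for any
  injective linear embedding, and is invariant to orthogonal latent
  transforms; under general invertible transforms of a *non-injective*
  latent space the PCA-based variance weights change, and the score
  with them — an inherent property of the weighting, not a bug.
* **DSA** — delay-embed each trajectory set (10 delays, stride 1 by
  default), fit a one-step linear dynamics matrix by least squares
  (optionally rank-reduced), and minimize ‖Ax − C Ay C⁻¹‖_F over
  orthogonal C.  Reported in angular form
  arccos(⟨Ax, C*AyC*ᵀ⟩ / ‖Ax‖‖Ay‖) ∈ [0, π/2].  The optimizer is
  projected gradient ascent with polar retraction from 5 starts
  covering both components of O(n), plus, for n ≤ 16, an L-BFGS polish
  in the skew-symmetric tangent parametrization with very tight
  tolerances — the objective can be extremely flat near its maximum,
  and first-order ascent alone stalls ~1e-3 rad short.

## Fixed points

Fixed points of a state-update map at a static input u* minimize the
kinetic energy q(z) = ½‖F(z, u*) − z‖².  The finder runs batched Adam
descent from trajectory-sampled initializations, then Newton iteration
on F(z) − z = 0 with per-candidate backtracking.  Newton is what makes
the census reliable: genuine fixed points converge to q ≈ 1e-30
(machine precision), while slow points stall around 1e-8.  The keep
threshold is therefore q < 1e-14·D — far below the slow-point floor —
after which duplicates merge greedily within a 1e-2 Euclidean radius
and stability follows the discrete-time rule (all |eig| < 1 of the
state Jacobian; a continuous-time Re(λ) < 0 rule is available for flow
fields).  With a loose 1e-8-style threshold the census of a trained
flip-flop network is polluted by hundreds of slow-manifold points per
attractor.

For the canonical 3BFF network this procedure returns 8 stable fixed
points (the memory states, vertices of a cube in state space) and
typically 12 unstable saddles (the cube's edges).

## Experiments and problem sizes

The harness reproduces three result patterns at desk scale, all on one
CPU:

1. **Hidden-size sweep** (`run_sweep`): neural-ODE autoencoders with
   D̂ ∈ {3, 8, 64}, two seeds each, on one 3BFF dataset (250 trials of
   100 steps, 40 neurons).  Reconstruction (rate R², co-BPS) rises from
   D̂=3 to D̂=8 (underfitting relieved); simplicity (state R²,
   cycle-consistency) falls from D̂=8 to D̂=64 (feature invention);
   the ground-truth-requiring and ground-truth-free metric of each pair
   correlate strongly across the sweep.
2. **Input-inference sweep** (`run_input_inference_experiment`): the
   input-inferring autoencoder across a log-spaced grid of KL weights
   ({0.003, 0.3, 3, 30} in the test suite).  The bottom of the grid
   must reach the regime where inputs are essentially free — against a
   sharply-trained ground-truth network, mild penalties already leave
   the attractors intact, so the grid extends low enough that the
   generator demonstrably loses them.
   Input R² is scored against *effective* inputs — the sign-reversing
   pulses, since a pulse that re-asserts the current bit leaves no
   evidence in the dynamics — with the true-pulse variant also
   reported.  Expected pattern: input R² rises with the KL weight
   (sparsity forces the controller to stop explaining intrinsic
   dynamics as input), then falls when the penalty is strong enough to
   underfit; and only models with accurate inputs reproduce the 8-point
   stable fixed-point structure in their generator, while low-penalty
   models absorb the dynamics into their inputs (dynamical
   misattribution) and show fewer attractors.
3. **Linear parameter recovery**: the linear autoencoder on data from a
   linear ground-truth system (12 latent dimensions fully observed by
   12 neurons, 300 trials) recovers state R² ≥ 0.95 and rate R² ≥ 0.8.

Problem sizes were chosen so the full test suite and the acceptance
script each run in well under half an hour on one CPU; they are stated
in the test fixtures and `scripts/acceptance.py`.

## What the synthetic setting does not show

The simulator emulates low-dimensional latent dynamics, linear-
exponential rate embeddings, and Poisson count noise.  It does not
emulate non-Poisson variability (over/under-dispersion), temporal
coding, nonstationarity across trials, electrode noise or sorting
artifacts, or nonlinear embeddings — the embedding is linear in the
latents by construction, which is exactly the assumption the linear
metrics (state R², cycle-consistency) lean on.  Passing these tests
therefore shows a model can recover dynamics *under the benchmark's
generative assumptions*; it does not certify performance on biological
recordings.

## Numerical choices

* All computation is float64 numpy; trainable models run on a small
  tape-based reverse-mode autodiff engine written for this package.
* Poisson NLL drops the log y! term (constant in the rates) everywhere;
  co-BPS uses the difference of log-likelihoods so the term cancels
  exactly.
* Log-rates are capped at 3 (≈20 spikes/bin) inside DD models to keep
  early training finite.
* Degenerate inputs raise: all-zero-variance R² inputs, zero held-out
  spikes in co-BPS, zero dynamics matrices in DSA, empty neuron splits.
* Seeds: every stochastic component (trial generation, initialization,
  spiking noise, splits, dropout, posterior sampling, optimizer
  restarts) takes an explicit seed; experiment functions derive
  sub-seeds by fixed offsets from one master seed.
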