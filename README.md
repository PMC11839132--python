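# ctdbench

Benchmarking **data-driven models of neural population dynamics** against
simulated ground truth.

Systems neuroscience increasingly explains neural computation through
*latent dynamics*: a low-dimensional state **z** evolving under a rule
**ż = f(z, u)** with external inputs **u**, read out into behavior by
**x = h(z)** and embedded into the spiking of N neurons by a rate map
**n = g(z)** with Poisson noise, **y ~ Poisson(n)**.  A growing family
of models (sequential autoencoders, LFADS-style networks, neural ODEs)
tries to invert this: infer **f̂**, **ĝ**, **ẑ** — and, when inputs are
unobserved, **û** — from spikes alone.  Validating those models needs
synthetic systems that actually *compute* something, and metrics that
catch the characteristic failure modes:

* **underfitting** — the model misses features of the true system;
* **feature invention** — the model's latents contain structure the
  true system never had (and reconstruction alone rewards it!);
* **dynamical misattribution** — inferred inputs absorb what the true
  system generates intrinsically, so **f̂** is wrong even though **ẑ**
  looks right.

`ctdbench` provides the whole loop, self-contained and seeded:

1. **Task environments** — 1/3-bit flip-flop memory and a simplified
   MemoryPro/MemoryAnti pair — generate inputs **u** and targets **x**.
2. **Task-trained (TT) models** (GRU / linear / neural-ODE) learn the
   task and become the ground-truth dynamical system.
3. A calibrated **linear-exponential embedding** turns TT hidden
   trajectories into Poisson spiking datasets (HDF5), split into
   held-in/held-out neurons and train/validation trials.
4. **Data-driven (DD) baselines** — linear, GRU, neural-ODE sequential
   autoencoders, plus an input-inferring autoencoder with a controller/
   generator split and a Student-t (df = 5) sparse prior on **û**.
5. **Metrics**: variance-weighted Rate/State/Input R², co-smoothing
   bits-per-spike, cycle-consistency, and the angular Dynamical
   Similarity Analysis (DSA) distance
   `min_{C∈O(n)} ‖A_x − C A_y C⁻¹‖_F`, plus a kinetic-energy
   fixed-point finder with Newton refinement and stability
   classification.

See `docs/methods.md` for the model details, defaults, and caveats.

## Worked example

Train the ground-truth network on the 3-bit flip-flop, simulate
spiking, train a neural-ODE autoencoder, and score it:

```python
import numpy as np
from ctdbench.experiments import build_3bff_dataset
from ctdbench.dd import DDTrainConfig, infer_dd, init_dd_model, train_dd_model
from ctdbench.metrics import co_bps, cycle_consistency, rate_r2, state_r2
from ctdbench.sim import VALID

ds, tt, batch = build_3bff_dataset(seed=0, n_trials=300, trial_len=80)
print("TT task score:", round(ds.provenance["tt_score"], 4))

model = init_dd_model("node-sae", d_hidden=8, n_neurons=ds.n_neurons,
                      n_heldin=int(ds.heldin_mask.sum()), d_u=3, seed=0,
                      vf_width=32, d_enc=16, ic_enc_window=30)
model, log = train_dd_model(model, ds, seed=0,
                            train_cfg=DDTrainConfig(max_epochs=150,
                                                    patience=150))
va = ds.trials(VALID)
out = infer_dd(model, ds, trials=va)
ho = ds.heldout_mask()
print("rate R2 :", round(rate_r2(ds.n[va], out.n_hat), 3))
print("state R2:", round(state_r2(ds.z[va], out.z_hat), 3))
print("co-BPS  :", round(co_bps(ds.y[va][:, :, ho], out.n_hat[:, :, ho]), 3))
print("cycle   :", round(cycle_consistency(out.z_hat, out.n_hat), 3))
```

```
TT task score: 0.9991
rate R2 : 0.446
state R2: 0.857
co-BPS  : 0.242
cycle   : 1.0
```

The TT score is the fraction of time steps on which the trained
network's output sign matches all three memory bits.  Rate R² and
co-BPS measure reconstruction (1 = perfect rates; co-BPS > 0 beats the
mean-rate predictor on held-out neurons); state R² and
cycle-consistency measure simplicity — how much of the inferred latent
variance the true system (or the model's own rates) can explain.  An
8-dimensional neural ODE reconstructs this task well without inventing
features; shrinking it to 3 dimensions underfits, growing it to 64
invents latent structure and drags both simplicity scores down
(`ctdbench.experiments.run_sweep` reproduces the whole pattern).

A `ctdb` command-line interface wraps the same pipeline
(`ctdb gen-env`, `train-tt`, `simulate`, `train-dd`, `evaluate`,
`find-fps`, `sweep`), each taking a YAML config and `--seed`.

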