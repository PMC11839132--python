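"""Scripted, seeded experiments: dataset builds, sweeps, input inference.

This module wires the pipeline end to end at desk scale:

* :func:`build_3bff_dataset` — train a gated recurrent network on the
  three-bit flip-flop task to a sign-match criterion, record its hidden
  trajectories, embed them into Poisson spiking, and split neurons and
  trials.
* :func:`run_sweep` — train a grid of data-driven models (hyperparameter
  values × seeds) on one dataset and tabulate every applicable metric.
* :func:`run_input_inference_experiment` — train input-inferring
  autoencoders across a grid of KL-penalty weights, score input accuracy
  against true and *effective* inputs, and compare the fixed-point
  structure of each trained generator at zero inferred input.

"Effective" inputs are the pulses that actually flip a memory bit; a
pulse that re-asserts the current sign changes nothing, so an
input-inferring model has no evidence for it.  Input accuracy is
therefore scored against the sign-reversing pulse train by default (the
true-pulse variant is also reported).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dd import DDTrainConfig, infer_dd, init_dd_model, train_dd_model
from .fixed_points import (FPConfig, classify_and_dedupe, find_fixed_points,
                           fp_summary, sample_trajectory_states)
from .metrics import (co_bps, cycle_consistency, input_r2, rate_r2, state_r2)
from .sim import (NeuralDataset, VALID, build_embedding, simulate_spikes,
                  split_neurons)
from .tasks import EnvConfig, TrialBatch, gen_flipflop_trials
from .tt import TrainConfig, TTModel, train_tt_model

__all__ = ["SweepSpec", "build_3bff_dataset", "effective_inputs", "run_sweep",
           "run_input_inference_experiment"]


def effective_inputs(batch: TrialBatch) -> np.ndarray:
    """Sign-reversing pulses only (the inputs that change the state).

    A pulse is effective iff it flips the target sign on its channel;
    the forced t=0 pulse sets the initial state and is not counted.
    """
    eff = np.zeros_like(batch.pulses)
    flip = batch.x[:, 1:] != batch.x[:, :-1]
    eff[:, 1:][flip] = batch.pulses[:, 1:][flip]
    return eff


# -- canonical 3BFF dataset ---------------------------------------------------

def build_3bff_dataset(seed: int = 0, n_trials: int = 1000,
                       trial_len: int = 200, n_neurons: int = 40,
                       d_latent: int = 64, target_mean_rate: float = 10.0,
                       frac_heldout: float = 0.25,
                       tt_criterion: float = 0.999,
                       tt_max_iters: int = 2500,
                       tt_trial_len: int = 200,
                       ) -> tuple[NeuralDataset, TTModel, TrialBatch]:
    """Train a 3BFF ground-truth network and simulate spiking from it.

    Returns ``(dataset, tt_model, trial_batch)``.  Fully seeded: the
    environment, task training, embedding, spiking noise, and splits all
    derive their generators from ``seed``.

    ``tt_trial_len`` controls the trials the ground-truth network is
    *trained* on, independently of the simulated dataset's
    ``trial_len``: long training trials are what force every memory
    state to crystallize into a genuine attractor (short ones leave
    some states as slow manifolds).
    """
    env = EnvConfig(trial_len=tt_trial_len, seed=seed)
    tt = TTModel("gru", d_latent, 3, 3, seed=seed)
    tt, log = train_tt_model(
        tt, env,
        TrainConfig(max_iters=tt_max_iters, lr=3e-3, val_every=50,
                    criterion=tt_criterion),
        seed=seed)
    batch = gen_flipflop_trials(
        EnvConfig(trial_len=trial_len, seed=seed + 10_007), n_trials, 3)
    z, _ = tt.rollout(batch.u)
    spec = build_embedding(d_latent, n_neurons, target_mean_rate,
                           seed=seed + 1, calib_z=z, dt=env.dt)
    ds = simulate_spikes(z, spec, seed=seed + 2, u=batch.u,
                         provenance={"task": "3bff", "env_seed": env.seed,
                                     "tt_seed": seed,
                                     "tt_score": log.final_score})
    split_neurons(ds, frac_heldout=frac_heldout, seed=seed + 3)
    return ds, tt, batch


# -- hyperparameter sweep -----------------------------------------------------

@dataclass
class SweepSpec:
    arch: str = "node-sae"
    param: str = "d_hidden"
    values: tuple = (3, 5, 8, 16, 32, 64)
    n_seeds: int = 5
    d_u: int = 3
    metrics: tuple = ("rate_r2", "state_r2", "co_bps", "cycle_consistency")
    train_cfg: DDTrainConfig = field(default_factory=DDTrainConfig)
    model_kwargs: dict = field(default_factory=dict)
    out_path: str | None = None

    def __post_init__(self):
        if not self.values:
            raise ValueError("values must be non-empty")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")


def _score_model(model, ds: NeuralDataset, metric_names) -> dict:
    va = ds.trials(VALID)
    out = infer_dd(model, ds, trials=va)
    ho = ds.heldout_mask()
    scores = {}
    for name in metric_names:
        if name == "rate_r2":
            scores[name] = rate_r2(ds.n[va], out.n_hat)
        elif name == "state_r2":
            scores[name] = state_r2(ds.z[va], out.z_hat)
        elif name == "co_bps":
            scores[name] = co_bps(ds.y[va][:, :, ho], out.n_hat[:, :, ho])
        elif name == "cycle_consistency":
            scores[name] = cycle_consistency(out.z_hat, out.n_hat)
        else:
            raise ValueError(f"unknown sweep metric {name!r}")
    return scores


def run_sweep(ds: NeuralDataset, spec: SweepSpec, base_seed: int = 0
              ) -> pd.DataFrame:
    """Train ``len(values) × n_seeds`` DD models and tabulate metrics.

    One row per model; a cell that fails to train is flagged in the
    ``failed`` column and the sweep continues.
    """
    n_heldin = int(ds.heldin_mask.sum())
    rows = []
    for value in spec.values:
        for s in range(spec.n_seeds):
            seed = base_seed + s
            row = {spec.param: value, "seed": seed, "arch": spec.arch,
                   "failed": False}
            t0 = time.time()
            try:
                kwargs = dict(spec.model_kwargs)
                kwargs[spec.param] = value
                model = init_dd_model(
                    spec.arch, n_neurons=ds.n_neurons, n_heldin=n_heldin,
                    d_u=spec.d_u, seed=seed, **kwargs)
                model, log = train_dd_model(model, ds, seed=seed,
                                            train_cfg=spec.train_cfg)
                row.update(_score_model(model, ds, spec.metrics))
                row["epochs"] = len(log["train_loss"])
                row["aborted"] = log["aborted"]
            except Exception as exc:   # noqa: BLE001 - sweep must continue
                row["failed"] = True
                row["error"] = str(exc)
            row["wall_seconds"] = time.time() - t0
            rows.append(row)
    table = pd.DataFrame(rows)
    if spec.out_path:
        table.to_csv(spec.out_path, index=False)
    return table


# -- input-inference experiment -----------------------------------------------

def run_input_inference_experiment(
        ds: NeuralDataset, batch: TrialBatch, kl_weights,
        seed: int = 0, d_hidden: int = 32, d_u: int = 3,
        train_cfg: DDTrainConfig | None = None,
        fp_n_inits: int = 512, out_path: str | None = None):
    """KL-penalty sweep for input-inferring autoencoders.

    For each weight: train, score reconstruction (co-bps), simplicity
    (cycle-consistency) and input accuracy (against effective and true
    inputs), then find fixed points of the trained generator at zero
    inferred input and count the stable ones.

    Returns ``(table, fp_reports)`` where ``fp_reports[kl_weight]`` is a
    JSON-ready fixed-point summary.
    """
    tc = train_cfg or DDTrainConfig()
    va = ds.trials(VALID)
    ho = ds.heldout_mask()
    u_eff = effective_inputs(batch)
    n_heldin = int(ds.heldin_mask.sum())
    rows = []
    fp_reports = {}
    for klw in kl_weights:
        row = {"kl_weight": klw, "failed": False}
        t0 = time.time()
        try:
            model = init_dd_model(
                "input-infer-sae", d_hidden=d_hidden, n_neurons=ds.n_neurons,
                n_heldin=n_heldin, d_u=d_u, seed=seed, kl_weight=klw)
            model, log = train_dd_model(model, ds, seed=seed, train_cfg=tc)
            out = infer_dd(model, ds, trials=va)
            row["co_bps"] = co_bps(ds.y[va][:, :, ho], out.n_hat[:, :, ho])
            row["cycle_consistency"] = cycle_consistency(out.z_hat, out.n_hat)
            row["input_r2"] = input_r2(u_eff[va], out.u_hat)
            row["input_r2_true"] = input_r2(ds.u[va], out.u_hat)
            row["mean_abs_u_hat"] = float(np.abs(out.u_hat).mean())
            row["epochs"] = len(log["train_loss"])

            inits = sample_trajectory_states(out.z_hat, fp_n_inits,
                                             seed=seed)
            fps = find_fixed_points(model.step, np.zeros(d_u), inits,
                                    FPConfig(seed=seed))
            reps = classify_and_dedupe(fps)
            report = fp_summary(reps)
            fp_reports[klw] = report
            row["n_stable_fps"] = report["n_stable"]
            row["n_unstable_fps"] = report["n_unstable"]
        except Exception as exc:   # noqa: BLE001
            row["failed"] = True
            row["error"] = str(exc)
        row["wall_seconds"] = time.time() - t0
        rows.append(row)
    table = pd.DataFrame(rows)
    if out_path:
        table.to_csv(out_path, index=False)
    return table, fp_reports
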