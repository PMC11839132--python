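"""Task-trained (TT) ground-truth dynamics models.

A TT model is a discrete-time latent dynamical system ``z_{t+1} = f(z_t,
u_t)`` with an affine readout ``x_t = h(z_t)``, trained by gradient
descent to solve a task environment.  Its hidden activity is the ground
truth from which spiking datasets are simulated.

Three architectures:

* ``gru`` — a gated recurrent unit; the workhorse that reliably solves
  the flip-flop and memory tasks.
* ``linear`` — ``z' = Az + Bu``; deliberately too weak for flip-flop
  (multistability is out of reach of a linear system), used to exhibit
  the underfitting failure mode.
* ``node`` — a neural ODE whose vector field is a one-hidden-layer MLP,
  integrated with a fixed-step 4th-order Runge-Kutta scheme, one step
  per time bin.

Trials are regenerated freshly at every training iteration (an
infinite-data regime), so TT training quality is limited by optimization,
not by a finite training set.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

from .autodiff import Adam, Tensor, concat, no_grad
from .tasks import (EnvConfig, TrialBatch, PHASE_RESP, gen_flipflop_trials,
                    gen_memory_trials)

__all__ = ["TTModel", "TrainConfig", "TrainLog", "init_tt_model",
           "train_tt_model", "eval_tt_performance", "save_model", "load_model"]

ARCHS = ("gru", "linear", "node")

_CKPT_VERSION = 1


def _uniform_fan_in(rng, fan_in, shape):
    lim = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-lim, lim, size=shape)


class TTModel:
    """Latent dynamical system with affine readout (see module docstring)."""

    def __init__(self, arch: str, d_latent: int, d_in: int, d_out: int,
                 seed: int = 0, vf_width: int = 64):
        if arch not in ARCHS:
            raise ValueError(f"unknown arch {arch!r}; choose from {ARCHS}")
        if min(d_latent, d_in, d_out) < 1:
            raise ValueError("all dimensions must be >= 1")
        self.arch = arch
        self.d_latent = d_latent
        self.d_in = d_in
        self.d_out = d_out
        self.seed = seed
        self.vf_width = vf_width
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(seed))

    def _init_params(self, rng):
        D, I, O = self.d_latent, self.d_in, self.d_out
        p = {}
        if self.arch == "gru":
            for gate in ("r", "z", "c"):
                p[f"W{gate}"] = _uniform_fan_in(rng, I, (I, D))
                p[f"U{gate}"] = _uniform_fan_in(rng, D, (D, D))
                p[f"b{gate}"] = np.zeros(D)
        elif self.arch == "linear":
            p["A"] = _uniform_fan_in(rng, D, (D, D))
            p["B"] = _uniform_fan_in(rng, I, (I, D))
        else:  # node
            H = self.vf_width
            p["W1"] = _uniform_fan_in(rng, D + I, (D + I, H))
            p["b1"] = np.zeros(H)
            p["W2"] = _uniform_fan_in(rng, H, (H, D))
            p["b2"] = np.zeros(D)
        p["C"] = _uniform_fan_in(rng, D, (D, O))
        p["d"] = np.zeros(O)
        self.params = {k: Tensor.param(v) for k, v in p.items()}

    # -- dynamics -------------------------------------------------------------
    def step(self, z: Tensor, u: Tensor) -> Tensor:
        """One state update z_{t+1} = f(z_t, u_t)."""
        p = self.params
        if self.arch == "gru":
            r = (u @ p["Wr"] + z @ p["Ur"] + p["br"]).sigmoid()
            g = (u @ p["Wz"] + z @ p["Uz"] + p["bz"]).sigmoid()
            c = (u @ p["Wc"] + (r * z) @ p["Uc"] + p["bc"]).tanh()
            return (1.0 - g) * z + g * c
        if self.arch == "linear":
            return z @ p["A"] + u @ p["B"]
        # node: RK4, one step per bin, unit step size
        def vf(zz):
            h = (concat([zz, u], axis=-1) @ p["W1"] + p["b1"]).tanh()
            return h @ p["W2"] + p["b2"]
        k1 = vf(z)
        k2 = vf(z + 0.5 * k1)
        k3 = vf(z + 0.5 * k2)
        k4 = vf(z + k3)
        return z + (k1 + 2.0 * k2 + 2.0 * k3 + k4) * (1.0 / 6.0)

    def readout(self, z: Tensor) -> Tensor:
        return z @ self.params["C"] + self.params["d"]

    def rollout(self, u: np.ndarray, z0: np.ndarray | None = None,
                with_grad: bool = False):
        """Run the dynamics over a batch of input sequences.

        Parameters
        ----------
        u : array [trials, time, d_in]
        z0 : optional initial state [trials, d_latent]; zeros by default.

        Returns ``(z, x)`` — with_grad=False: numpy arrays of latents
        (state *after* consuming u[:, t]) and outputs; with_grad=True:
        lists of per-step Tensors for building training losses.
        """
        B, T, _ = u.shape
        if z0 is None:
            z0 = np.zeros((B, self.d_latent))
        ctx = no_grad() if not with_grad else _nullcontext()
        with ctx:
            z = Tensor(z0)
            zs, xs = [], []
            for t in range(T):
                z = self.step(z, Tensor(u[:, t]))
                zs.append(z)
                xs.append(self.readout(z))
        if with_grad:
            return zs, xs
        return (np.stack([t.data for t in zs], axis=1),
                np.stack([t.data for t in xs], axis=1))

    def param_arrays(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def set_param_arrays(self, arrays: dict):
        for k, v in arrays.items():
            self.params[k].data = np.array(v, dtype=np.float64)


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *a):
        return False


def init_tt_model(arch: str, d_latent: int, d_in: int, d_out: int,
                  seed: int = 0, **kw) -> TTModel:
    """Seeded construction; identical seeds give identical parameters."""
    return TTModel(arch, d_latent, d_in, d_out, seed=seed, **kw)


@dataclass
class TrainConfig:
    max_iters: int = 3000
    batch_size: int = 64
    lr: float = 3e-3
    clip_norm: float = 1.0
    criterion: float = 0.95        # validation score to stop at
    val_every: int = 25
    val_trials: int = 64
    response_weight: float = 5.0   # memory tasks only
    n_bits: int = 3
    task: str = "flipflop"         # "flipflop" | "memory"


@dataclass
class TrainLog:
    loss: list = field(default_factory=list)       # per-iteration task loss
    val_iters: list = field(default_factory=list)
    val_score: list = field(default_factory=list)
    final_score: float = float("nan")
    wall_seconds: float = 0.0
    converged: bool = False


def _gen_batch(env: EnvConfig, tc: TrainConfig, n: int, seed: int) -> TrialBatch:
    cfg = EnvConfig(**{**asdict(env), "seed": seed})
    if tc.task == "flipflop":
        return gen_flipflop_trials(cfg, n, tc.n_bits)
    return gen_memory_trials(cfg, n)


def train_tt_model(model: TTModel, env: EnvConfig,
                   train_cfg: TrainConfig | None = None,
                   seed: int = 0) -> tuple[TTModel, TrainLog]:
    """Gradient-train a TT model on freshly generated trials.

    Stops when the validation task score reaches ``criterion`` or at
    ``max_iters``.  Raises on a non-finite loss.
    """
    tc = train_cfg or TrainConfig()
    log = TrainLog()
    t0 = time.time()
    val_batch = _gen_batch(env, tc, tc.val_trials, seed=seed + 999_983)
    opt = Adam(list(model.params.values()), lr=tc.lr, clip_norm=tc.clip_norm)

    for it in range(tc.max_iters):
        batch = _gen_batch(env, tc, tc.batch_size, seed=seed + it)
        _, xs = model.rollout(batch.u, with_grad=True)
        w = np.ones(batch.x.shape[:2])
        if tc.task == "memory":
            w[batch.phase_labels == PHASE_RESP] = tc.response_weight
        wt = w[:, :, None] / (w.sum() * batch.x.shape[2])
        loss = None
        for t, xt in enumerate(xs):
            term = ((xt - batch.x[:, t]) ** 2 * wt[:, t]).sum()
            loss = term if loss is None else loss + term
        lval = float(loss.data)
        if not np.isfinite(lval):
            raise RuntimeError(
                f"task loss diverged (non-finite) at iteration {it}")
        log.loss.append(lval)
        opt.zero_grad()
        loss.backward()
        opt.step()

        if (it + 1) % tc.val_every == 0 or it == tc.max_iters - 1:
            score = eval_tt_performance(model, val_batch)
            log.val_iters.append(it)
            log.val_score.append(score)
            if score >= tc.criterion:
                log.converged = True
                break

    log.final_score = eval_tt_performance(model, val_batch)
    log.wall_seconds = time.time() - t0
    return model, log


def eval_tt_performance(model: TTModel, batch: TrialBatch,
                        angle_tol_deg: float = 20.0,
                        fix_tol: float = 0.3) -> float:
    """Task score in [0, 1].

    Flip-flop: fraction of (trial, time, channel) entries where the sign
    of the readout matches the target sign (sign(0) counts as wrong).
    Memory: fraction of response-phase steps where the output angle is
    within ``angle_tol_deg`` of the target angle *and* the fixation
    output is within ``fix_tol`` of the fixation target at every step of
    the trial.
    """
    _, x_hat = model.rollout(batch.u)
    if (batch.phase_labels == 0).all():   # flip-flop: targets are in {-1, +1}
        return float(np.mean(np.sign(x_hat) == np.sign(batch.x)))
    resp = batch.phase_labels == PHASE_RESP
    ang_hat = np.arctan2(x_hat[..., 2], x_hat[..., 1])
    ang_true = np.arctan2(batch.x[..., 2], batch.x[..., 1])
    dang = np.abs(np.angle(np.exp(1j * (ang_hat - ang_true))))
    ang_ok = (dang <= np.deg2rad(angle_tol_deg))[resp]
    fix_ok = np.abs(x_hat[..., 0] - batch.x[..., 0]) <= fix_tol
    trial_fix_ok = fix_ok.all(axis=1)
    ok = ang_ok & np.repeat(trial_fix_ok, resp.sum(axis=1))
    return float(ok.mean())


# -- checkpoints --------------------------------------------------------------

def save_model(model, path):
    """Write a model checkpoint (parameter arrays + architecture config).

    Shared by TT and DD models: anything exposing ``param_arrays`` /
    ``set_param_arrays`` and the config attributes serializes here.
    """
    with h5py.File(path, "w") as f:
        g = f.create_group("params")
        for k, v in model.param_arrays().items():
            g.create_dataset(k, data=v)
        f.attrs["config"] = json.dumps(model_config(model))
        f.attrs["ckpt_version"] = _CKPT_VERSION


def model_config(model) -> dict:
    cfg = {"class": type(model).__name__, "arch": model.arch,
           "seed": model.seed}
    for name in ("d_latent", "d_in", "d_out", "d_hidden", "vf_width",
                 "n_neurons", "n_heldin", "d_u", "input_mode", "d_enc",
                 "kl_weight", "prior_df", "prior_scale", "kl_ic_weight",
                 "ic_enc_window"):
        if hasattr(model, name):
            cfg[name] = getattr(model, name)
    return cfg


def load_model(path, factory=None):
    """Load a checkpoint written by :func:`save_model`.

    ``factory(config) -> model`` builds the empty model; by default TT
    models are reconstructed from their stored config.
    """
    with h5py.File(path, "r") as f:
        if "ckpt_version" not in f.attrs:
            raise ValueError(f"{path}: not a ctdbench checkpoint "
                             "(missing ckpt_version)")
        if int(f.attrs["ckpt_version"]) != _CKPT_VERSION:
            raise ValueError(f"{path}: unsupported checkpoint version")
        cfg = json.loads(f.attrs["config"])
        arrays = {k: f["params"][k][:] for k in f["params"]}
    if factory is not None:
        model = factory(cfg)
    elif cfg.get("class") == "TTModel":
        model = TTModel(cfg["arch"], cfg["d_latent"], cfg["d_in"],
                        cfg["d_out"], seed=cfg["seed"],
                        vf_width=cfg.get("vf_width", 64))
    elif cfg.get("class") == "DDModel":
        from .dd import DDModel
        model = DDModel(
            cfg["arch"], cfg["d_hidden"], cfg["n_neurons"], cfg["n_heldin"],
            d_u=cfg.get("d_u", 0), seed=cfg.get("seed", 0),
            d_enc=cfg.get("d_enc", 32), vf_width=cfg.get("vf_width", 64),
            kl_weight=cfg.get("kl_weight", 1.0),
            prior_df=cfg.get("prior_df", 5.0),
            prior_scale=cfg.get("prior_scale", 1.0),
            kl_ic_weight=cfg.get("kl_ic_weight", 1.0),
            ic_enc_window=cfg.get("ic_enc_window"))
    else:
        raise ValueError(f"cannot reconstruct model class {cfg.get('class')!r} "
                         "without a factory")
    model.set_param_arrays(arrays)
    return model
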