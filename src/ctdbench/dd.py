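"""Data-driven (DD) sequential-autoencoder models.

A DD model is trained to reconstruct spiking from *held-in* neurons
only, while predicting rates for *all* neurons (held-in + held-out):
an encoder reads held-in spikes into an initial latent state, a latent
dynamics model ``f̂`` rolls the state forward, and an affine-exponential
readout ``ĝ`` maps latents to Poisson rates.  Architectures:

* ``linear-sae``   — affine latent dynamics (an LDS); the underfitting
  baseline for tasks that need multistability.
* ``recurrent-sae`` — GRU latent dynamics.
* ``node-sae``     — neural-ODE dynamics (MLP vector field, fixed-step
  RK4, one step per bin); latent size D̂ controls expressivity.
* ``input-infer-sae`` — a lightweight sequential autoencoder for the
  unknown-input setting: a bidirectional encoder produces a Gaussian
  posterior over the initial condition, a *controller* reads encoded
  held-in spikes and the current generator state to produce a per-step
  Gaussian posterior over inferred inputs û, and a recurrent *generator*
  consumes samples of û.  Divergence of the û posterior from a sparse
  Student-t prior is penalized with weight ``kl_weight`` — the knob that
  trades input sparsity against reconstruction.

The first three run in ``supplied`` input mode (they consume the true
external inputs u); the last runs in ``inferred`` mode and never sees u.

Training minimizes the Poisson negative log-likelihood of all-neuron
spikes (plus the KL terms in inferred mode) with early stopping on
validation NLL.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, concat, no_grad, split_steps
from .nn import BiGRUEncoder, GRUCell, Linear, MLP
from .sim import NeuralDataset, TRAIN, VALID

__all__ = ["DDModel", "DDOutput", "DDTrainConfig", "init_dd_model",
           "train_dd_model", "infer_dd"]

ARCHS = ("linear-sae", "recurrent-sae", "node-sae", "input-infer-sae")

_LOGRATE_MAX = 3.0      # spikes/bin cap on exp(lograte) ~ e^3 ≈ 20


@dataclass
class DDOutput:
    """Inferred latents, rates (spikes/bin), and inputs for a batch."""

    z_hat: np.ndarray
    n_hat: np.ndarray
    u_hat: np.ndarray | None = None
    losses: dict = field(default_factory=dict)


@dataclass
class DDTrainConfig:
    max_epochs: int = 500
    batch_size: int = 64
    lr: float = 5e-3
    lr_decay: float = 0.999      # multiplicative, per epoch
    clip_norm: float = 5.0
    patience: int = 50           # epochs without valid-NLL improvement
    kl_ramp_epochs: int = 0      # optional linear ramp of kl_weight
    input_dropout: float = 0.25  # Bernoulli drop of encoder spike inputs
                                 # (training only); curbs encoder overfit
                                 # to single-trial spike noise


class DDModel:
    """Sequential autoencoder with pluggable latent dynamics."""

    def __init__(self, arch: str, d_hidden: int, n_neurons: int,
                 n_heldin: int, d_u: int = 0, seed: int = 0,
                 d_enc: int = 32, vf_width: int = 64, ctrl_width: int = 32,
                 kl_weight: float = 1.0, prior_df: float = 5.0,
                 prior_scale: float = 1.0, kl_ic_weight: float = 1.0,
                 ic_enc_window: int | None = None):
        if arch not in ARCHS:
            raise ValueError(f"unknown arch {arch!r}; choose from {ARCHS}")
        if d_hidden < 1:
            raise ValueError("d_hidden must be >= 1")
        self.arch = arch
        self.d_hidden = d_hidden
        self.n_neurons = n_neurons
        self.n_heldin = n_heldin
        self.d_u = d_u
        self.seed = seed
        self.d_enc = d_enc
        self.vf_width = vf_width
        self.kl_weight = kl_weight
        self.kl_ic_weight = kl_ic_weight
        self.prior_df = prior_df
        self.prior_scale = prior_scale
        # with supplied inputs the IC encoder only informs the initial
        # state, so it may read just the first steps of the trial
        self.ic_enc_window = ic_enc_window
        self.input_mode = "inferred" if arch == "input-infer-sae" else "supplied"

        rng = np.random.default_rng(seed)
        D = d_hidden
        self.ic_encoder = BiGRUEncoder(rng, n_heldin, d_enc)
        self.ic_head = Linear(rng, 2 * d_enc, 2 * D)   # Gaussian IC posterior
        if arch == "linear-sae":
            self.A = Linear(rng, D, D)
            self.B = Linear(rng, max(d_u, 1), D)
        elif arch in ("recurrent-sae", "input-infer-sae"):
            self.gen = GRUCell(rng, max(d_u, 1), D)
        else:  # node-sae
            self.vf = MLP(rng, [D + d_u, vf_width, D])
        if self.input_mode == "inferred":
            self.ci_encoder = BiGRUEncoder(rng, n_heldin, d_enc)
            self.controller = MLP(rng, [2 * d_enc + D, ctrl_width, 2 * d_u])
        self.readout = Linear(rng, D, n_neurons)

    # -- parameters -----------------------------------------------------------
    def params(self) -> list[Tensor]:
        ps = self.ic_encoder.params() + self.ic_head.params() \
            + self.readout.params()
        if self.arch == "linear-sae":
            ps += self.A.params() + self.B.params()
        elif self.arch in ("recurrent-sae", "input-infer-sae"):
            ps += self.gen.params()
        else:
            ps += self.vf.params()
        if self.input_mode == "inferred":
            ps += self.ci_encoder.params() + self.controller.params()
        return ps

    def param_arrays(self) -> dict:
        return {str(i): p.data.copy() for i, p in enumerate(self.params())}

    def set_param_arrays(self, arrays: dict):
        for i, p in enumerate(self.params()):
            p.data = np.array(arrays[str(i)], dtype=np.float64)

    # -- dynamics (exposed for fixed-point analysis) --------------------------
    def step(self, z: Tensor, u: Tensor) -> Tensor:
        """One latent state update ẑ_{t+1} = f̂(ẑ_t, u_t)."""
        if self.arch == "linear-sae":
            return self.A(z) + self.B(u)
        if self.arch in ("recurrent-sae", "input-infer-sae"):
            return self.gen(z, u)
        def vf(zz):
            return self.vf(concat([zz, u], axis=-1)) if self.d_u > 0 \
                else self.vf(zz)
        k1 = vf(z)
        k2 = vf(z + 0.5 * k1)
        k3 = vf(z + 0.5 * k2)
        k4 = vf(z + k3)
        return z + (k1 + 2.0 * k2 + 2.0 * k3 + k4) * (1.0 / 6.0)

    def lograte(self, z: Tensor) -> Tensor:
        return self.readout(z).clip_max(_LOGRATE_MAX)

    # -- forward pass ---------------------------------------------------------
    def forward(self, y_in, u: np.ndarray | None = None,
                sample: bool = False, rng: np.random.Generator | None = None):
        """Roll the autoencoder over a batch.

        ``y_in``: held-in spikes [B, T, n_heldin] (array or Tensor).
        ``u``: true inputs (supplied mode only; must be None in inferred
        mode).  ``sample=True`` draws reparameterized samples of the
        stochastic nodes (training); otherwise posterior means are used.

        Returns a dict with per-step Tensor lists ``z``, ``lograte``,
        ``u_hat`` and scalar Tensors ``kl_ic``, ``kl_u`` (inferred mode).
        """
        if self.input_mode == "supplied":
            if u is None and self.d_u > 0:
                raise ValueError("supplied-input model requires u")
        elif u is not None:
            raise ValueError("inferred-input model must not receive u")
        Y = y_in if isinstance(y_in, Tensor) else Tensor(np.asarray(y_in))
        B, T, _ = Y.shape
        if sample and rng is None:
            rng = np.random.default_rng(0)

        Y_ic = Y if self.ic_enc_window is None else Y[:, :self.ic_enc_window]
        _, enc_final = self.ic_encoder(Y_ic)
        ic = self.ic_head(enc_final)
        mu, logvar = ic[:, :self.d_hidden], ic[:, self.d_hidden:]
        logvar = logvar.clip_max(4.0).clip_min(-10.0)
        if sample:
            eps = rng.standard_normal((B, self.d_hidden))
            z = mu + (logvar * 0.5).exp() * Tensor(eps)
        else:
            z = mu
        kl_ic = 0.5 * (mu**2 + logvar.exp() - logvar - 1.0).sum() * (1.0 / B)
        if self.input_mode == "inferred":
            ci_feats, _ = self.ci_encoder(Y)

        # precompute input-side projections where the inputs are known
        u_proj = None
        if self.input_mode == "supplied" and self.d_u > 0:
            if self.arch == "recurrent-sae":
                u_proj = self.gen.project_inputs(u)
            elif self.arch == "linear-sae":
                flat = Tensor(u).reshape(B * T, self.d_u)
                u_proj = split_steps(self.B(flat).reshape(B, T, self.d_hidden))

        zs, lr, u_hats = [], [], []
        kl_u = Tensor(0.0)
        for t in range(T):
            if self.input_mode == "inferred":
                ctrl_in = concat([ci_feats[t], z], axis=-1)
                out = self.controller(ctrl_in)
                mu_u, logvar_u = out[:, :self.d_u], out[:, self.d_u:]
                logvar_u = logvar_u.clip_max(4.0).clip_min(-10.0)
                if sample:
                    eps = rng.standard_normal((B, self.d_u))
                    u_t = mu_u + (logvar_u * 0.5).exp() * Tensor(eps)
                    kl_u = kl_u + self._kl_u_mc(u_t, mu_u, logvar_u, eps) * (1.0 / B)
                else:
                    u_t = mu_u
                u_hats.append(u_t)
                z = self.step(z, u_t)
            elif self.arch == "recurrent-sae" and u_proj is not None:
                z = self.gen.step(z, u_proj[t])
            elif self.arch == "linear-sae" and u_proj is not None:
                z = self.A(z) + u_proj[t]
            elif self.d_u > 0:
                z = self.step(z, Tensor(u[:, t]))
            else:
                z = self.step(z, Tensor(np.zeros((B, 1))))
            zs.append(z)
            lr.append(self.lograte(z))
        return {"z": zs, "lograte": lr, "u_hat": u_hats,
                "kl_ic": kl_ic, "kl_u": kl_u}

    def _kl_u_mc(self, u_t: Tensor, mu: Tensor, logvar: Tensor,
                 eps: np.ndarray) -> Tensor:
        """Single-sample KL(q ‖ Student-t prior); no closed form exists.

        log q at the reparameterized sample depends on parameters only
        through logvar; log p is the Student-t logpdf at the sample.
        """
        df, s = self.prior_df, self.prior_scale
        log_q = (-(0.5 * math.log(2 * math.pi)) - logvar * 0.5
                 - Tensor(0.5 * eps**2)).sum()
        const = (math.lgamma((df + 1) / 2) - math.lgamma(df / 2)
                 - 0.5 * math.log(df * math.pi) - math.log(s))
        log_p = (const - ((u_t * (1.0 / s))**2 * (1.0 / df) + 1.0).log()
                 * ((df + 1) / 2)).sum()
        return log_q - log_p


def init_dd_model(arch: str, d_hidden: int, n_neurons: int, n_heldin: int,
                  d_u: int = 0, seed: int = 0, **hp) -> DDModel:
    """Seeded construction of a DD model (see :class:`DDModel`)."""
    return DDModel(arch, d_hidden, n_neurons, n_heldin, d_u=d_u,
                   seed=seed, **hp)


def _poisson_nll(lr_steps: list[Tensor], y: np.ndarray) -> Tensor:
    """Mean Poisson NLL (per element) over all neurons and steps."""
    B, T, N = y.shape
    scale = 1.0 / (B * T * N)
    total = None
    for t, lr_t in enumerate(lr_steps):
        term = (lr_t.exp() - lr_t * Tensor(y[:, t])).sum() * scale
        total = term if total is None else total + term
    return total


def train_dd_model(model: DDModel, ds: NeuralDataset, seed: int = 0,
                   train_cfg: DDTrainConfig | None = None):
    """Train on the dataset's train trials; early-stop on valid NLL.

    The encoder (and controller) read held-in spikes only; the loss is
    the all-neuron Poisson NLL plus, in inferred mode, ``kl_weight``
    times the initial-condition and inferred-input KL terms (normalized
    per data element).  Returns ``(model, log)`` with the best-validation
    parameters restored; a non-finite loss aborts with the last good
    checkpoint.
    """
    tc = train_cfg or DDTrainConfig()
    if ds.heldin_mask is None or ds.trial_split is None:
        raise ValueError("dataset needs neuron and trial splits")
    if model.input_mode == "supplied" and model.d_u > 0 and ds.u.shape[-1] == 0:
        raise ValueError("supplied-input model but dataset has no inputs")
    rng = np.random.default_rng(seed)
    tr = ds.trials(TRAIN)
    va = ds.trials(VALID)
    y_in = ds.y[:, :, ds.heldin_mask].astype(np.float64)
    y_all = ds.y.astype(np.float64)
    T, N = y_all.shape[1], y_all.shape[2]
    # initialize readout bias at each neuron's mean log-rate
    mean_rate = np.maximum(y_all[tr].mean(axis=(0, 1)), 1e-4)
    model.readout.b.data = np.log(mean_rate)

    opt = Adam(model.params(), lr=tc.lr, clip_norm=tc.clip_norm)
    log = {"train_loss": [], "valid_nll": [], "best_epoch": -1,
           "aborted": False}
    best_nll = np.inf
    best_params = model.param_arrays()
    since_best = 0
    t0 = time.time()
    for epoch in range(tc.max_epochs):
        if tc.kl_ramp_epochs > 0:
            ramp = min(1.0, (epoch + 1) / tc.kl_ramp_epochs)
        else:
            ramp = 1.0
        order = rng.permutation(tr)
        ep_loss = 0.0
        nb = 0
        for i in range(0, len(order), tc.batch_size):
            idx = order[i:i + tc.batch_size]
            u = ds.u[idx] if model.input_mode == "supplied" and model.d_u > 0 \
                else None
            yb = y_in[idx]
            if tc.input_dropout > 0:
                keep = rng.random(yb.shape) >= tc.input_dropout
                yb = yb * keep / (1.0 - tc.input_dropout)
            out = model.forward(yb, u=u, sample=True, rng=rng)
            loss = _poisson_nll(out["lograte"], y_all[idx])
            loss = loss + out["kl_ic"] * (model.kl_ic_weight * ramp / (T * N))
            if model.input_mode == "inferred":
                loss = loss + out["kl_u"] * (model.kl_weight * ramp / (T * N))
            lval = float(loss.data)
            if not np.isfinite(lval):
                model.set_param_arrays(best_params)
                log["aborted"] = True
                log["wall_seconds"] = time.time() - t0
                return model, log
            ep_loss += lval
            nb += 1
            opt.zero_grad()
            loss.backward()
            opt.step()
        opt.lr *= tc.lr_decay
        log["train_loss"].append(ep_loss / max(nb, 1))

        with no_grad():
            u = ds.u[va] if model.input_mode == "supplied" and model.d_u > 0 \
                else None
            out = model.forward(y_in[va], u=u, sample=False)
            vnll = float(_poisson_nll(out["lograte"], y_all[va]).data)
        log["valid_nll"].append(vnll)
        if vnll < best_nll - 1e-6:
            best_nll = vnll
            best_params = model.param_arrays()
            log["best_epoch"] = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best > tc.patience:
                break
    model.set_param_arrays(best_params)
    log["wall_seconds"] = time.time() - t0
    return model, log


def infer_dd(model: DDModel, ds: NeuralDataset,
             trials: np.ndarray | None = None) -> DDOutput:
    """Deterministic inference (posterior means at stochastic nodes)."""
    if ds.heldin_mask is None:
        raise ValueError("dataset needs a held-in neuron mask")
    idx = np.arange(ds.n_trials) if trials is None else np.asarray(trials)
    y_in = ds.y[idx][:, :, ds.heldin_mask].astype(np.float64)
    if model.input_mode == "supplied" and model.d_u > 0:
        if ds.u.shape[-1] == 0:
            raise ValueError("supplied-input model but dataset has no inputs")
        u = ds.u[idx]
    else:
        u = None
    with no_grad():
        out = model.forward(y_in, u=u, sample=False)
    z = np.stack([t.data for t in out["z"]], axis=1)
    n = np.exp(np.stack([t.data for t in out["lograte"]], axis=1))
    u_hat = None
    if model.input_mode == "inferred":
        u_hat = np.stack([t.data for t in out["u_hat"]], axis=1)
    return DDOutput(z_hat=z, n_hat=n, u_hat=u_hat)
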