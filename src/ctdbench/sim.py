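"""Simulated Poisson spiking datasets from TT-model latent activity.

The embedding ``g`` maps latent state to firing rates with a
linear-exponential transform: ``n_neurons`` distinct hidden dimensions
are sampled without replacement, each scaled by a nonzero per-neuron
gain, offset, exponentiated, and used as the rate of a Poisson count
process (one count bin per simulation step).  Offsets are calibrated on
a provided latent batch so each neuron's mean rate matches a target (in
spikes/s); rates are capped at a physiological ceiling.

Because every gain is nonzero and dimensions are distinct, the true
embedding is injective on the selected dimensions — any extra structure
a data-driven model infers is its own invention, not an artifact of the
simulator having a null space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .tasks import TrialBatch
from .tt import TTModel

__all__ = ["EmbeddingSpec", "NeuralDataset", "run_tt_latents",
           "build_embedding", "simulate_spikes", "split_neurons",
           "write_dataset", "read_dataset"]

FORMAT_VERSION = 1

TRAIN, VALID = 0, 1


@dataclass
class EmbeddingSpec:
    """Linear-exponential latent-to-rate map (see module docstring).

    ``gain``/``offset`` are per-neuron; rates are
    ``exp(gain * z[sel] + offset)`` in spikes/s, clipped at
    ``clip_rate``, then multiplied by ``dt`` to give spikes/bin.
    """

    selected_dims: np.ndarray
    gain: np.ndarray
    offset: np.ndarray
    target_mean_rate: float = 10.0    # spikes/s
    clip_rate: float = 100.0          # spikes/s ceiling
    dt: float = 0.01                  # seconds per bin
    seed: int = 0

    def __post_init__(self):
        self.selected_dims = np.asarray(self.selected_dims, dtype=np.int64)
        self.gain = np.asarray(self.gain, dtype=np.float64)
        self.offset = np.asarray(self.offset, dtype=np.float64)
        if len(np.unique(self.selected_dims)) != len(self.selected_dims):
            raise ValueError("selected_dims must be unique")
        if not np.isfinite(self.gain).all() or (self.gain == 0).any():
            raise ValueError("gains must be finite and nonzero")

    @property
    def n_neurons(self) -> int:
        return len(self.selected_dims)

    def rates(self, z: np.ndarray) -> np.ndarray:
        """Rates in spikes/bin for latents z [..., d_latent]."""
        with np.errstate(over="ignore"):
            lam = np.exp(z[..., self.selected_dims] * self.gain + self.offset)
        return np.minimum(lam, self.clip_rate) * self.dt


@dataclass
class NeuralDataset:
    """Ground-truth latents, rates, spikes, inputs, and split masks."""

    z: np.ndarray                # [trials, time, D] true latents
    n: np.ndarray                # [trials, time, N] true rates (spikes/bin)
    y: np.ndarray                # [trials, time, N] spike counts
    u: np.ndarray                # [trials, time, d_u] true inputs
    heldin_mask: np.ndarray | None = None     # bool [N]
    trial_split: np.ndarray | None = None     # int [trials], TRAIN/VALID
    dt: float = 0.01
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.n < 0).any():
            raise ValueError("rates must be nonnegative")
        yi = np.asarray(self.y)
        if (yi < 0).any() or not np.array_equal(yi, np.round(yi)):
            raise ValueError("spike counts must be nonnegative integers")

    @property
    def n_neurons(self) -> int:
        return self.y.shape[2]

    @property
    def n_trials(self) -> int:
        return self.y.shape[0]

    def trials(self, split: int) -> np.ndarray:
        if self.trial_split is None:
            raise ValueError("dataset has no trial split; call split_neurons")
        return np.flatnonzero(self.trial_split == split)

    def heldout_mask(self) -> np.ndarray:
        return ~self.heldin_mask


def run_tt_latents(model: TTModel, batch: TrialBatch) -> np.ndarray:
    """Deterministic rollout; z[trial, t] is the state after u[trial, t]."""
    z, _ = model.rollout(batch.u)
    return z


def build_embedding(d_latent: int, n_neurons: int, target_mean_rate: float,
                    seed: int, calib_z: np.ndarray, dt: float = 0.01,
                    clip_rate: float = 100.0) -> EmbeddingSpec:
    """Sample a linear-exponential embedding calibrated on ``calib_z``.

    Gains are drawn with random sign and magnitude scaled by the inverse
    standard deviation of the selected latent dimension (so modulation
    depth is comparable across neurons); offsets are set so each neuron's
    mean rate over the calibration batch equals ``target_mean_rate``
    before clipping.
    """
    if n_neurons > d_latent:
        raise ValueError(
            f"cannot sample {n_neurons} dims from {d_latent} without replacement")
    rng = np.random.default_rng(seed)
    sel = rng.choice(d_latent, size=n_neurons, replace=False)
    zsel = calib_z.reshape(-1, calib_z.shape[-1])[:, sel]
    sd = zsel.std(axis=0)
    sd = np.where(sd < 1e-6, 1.0, sd)
    mag = rng.uniform(0.4, 1.2, size=n_neurons) / sd
    sign = rng.choice([-1.0, 1.0], size=n_neurons)
    gain = mag * sign

    def _offset(g):
        # mean exp-rate over calibration batch == target
        return np.log(target_mean_rate) - np.log(np.exp(zsel * g).mean(axis=0))

    # shrink gains where the rate tail would saturate the ceiling, so the
    # clip stays (essentially) inactive and the embedding injective
    cap = 0.9 * clip_rate
    for _ in range(30):
        q = np.quantile(np.exp(zsel * gain + _offset(gain)), 0.999, axis=0)
        hot = q > cap
        if not hot.any():
            break
        gain[hot] *= 0.9
    offset = _offset(gain)
    return EmbeddingSpec(selected_dims=sel, gain=gain, offset=offset,
                         target_mean_rate=target_mean_rate,
                         clip_rate=clip_rate, dt=dt, seed=seed)


def simulate_spikes(z: np.ndarray, spec: EmbeddingSpec, seed: int,
                    u: np.ndarray | None = None,
                    provenance: dict | None = None) -> NeuralDataset:
    """Poisson spikes from latents through the embedding; seeded."""
    # check the unclipped rates: the rate clip would mask an overflow
    eta = z[..., spec.selected_dims] * spec.gain + spec.offset
    with np.errstate(over="ignore"):
        lam_raw = np.exp(eta)
    n = spec.rates(z)
    bad = ~(np.isfinite(lam_raw).all(axis=(0, 1))
            & np.isfinite(n).all(axis=(0, 1)))
    if bad.any():
        raise FloatingPointError(
            f"non-finite rates for neurons {np.flatnonzero(bad).tolist()}")
    rng = np.random.default_rng(seed)
    y = rng.poisson(n).astype(np.int64)
    prov = dict(provenance or {})
    prov.setdefault("embedding", {
        "seed": spec.seed, "target_mean_rate": spec.target_mean_rate,
        "clip_rate": spec.clip_rate})
    prov["spike_seed"] = seed
    return NeuralDataset(
        z=z, n=n, y=y,
        u=u if u is not None else np.zeros(z.shape[:2] + (0,)),
        dt=spec.dt, provenance=prov)


def split_neurons(ds: NeuralDataset, frac_heldout: float = 0.25,
                  seed: int = 0, frac_valid: float = 0.2) -> NeuralDataset:
    """Assign held-in/held-out neurons and train/valid trials in place."""
    if not 0.0 < frac_heldout < 1.0:
        raise ValueError("frac_heldout must be in (0, 1)")
    rng = np.random.default_rng(seed)
    N = ds.n_neurons
    n_out = int(round(N * frac_heldout))
    if n_out == 0 or n_out == N:
        raise ValueError(
            f"frac_heldout={frac_heldout} leaves an empty neuron set for N={N}")
    mask = np.ones(N, dtype=bool)
    mask[rng.choice(N, size=n_out, replace=False)] = False
    ds.heldin_mask = mask

    n_trials = ds.n_trials
    n_valid = max(1, int(round(n_trials * frac_valid)))
    if n_valid >= n_trials:
        raise ValueError("trial split leaves no training trials")
    split = np.full(n_trials, TRAIN, dtype=np.int64)
    split[rng.choice(n_trials, size=n_valid, replace=False)] = VALID
    ds.trial_split = split
    ds.provenance["split_seed"] = seed
    return ds


def write_dataset(ds: NeuralDataset, path, manifest: bool = True):
    """HDF5 layout: data/{z,n,y,u}, masks/{heldin,trial_split}, attrs."""
    with h5py.File(path, "w") as f:
        g = f.create_group("data")
        for name in ("z", "n", "y", "u"):
            g.create_dataset(name, data=getattr(ds, name))
        m = f.create_group("masks")
        if ds.heldin_mask is not None:
            m.create_dataset("heldin", data=ds.heldin_mask)
        if ds.trial_split is not None:
            m.create_dataset("trial_split", data=ds.trial_split)
        f.attrs["dt"] = ds.dt
        f.attrs["provenance"] = json.dumps(ds.provenance, default=str)
        f.attrs["format_version"] = FORMAT_VERSION
    if manifest:
        side = str(path) + ".manifest.json"
        with open(side, "w") as fh:
            json.dump({"format_version": FORMAT_VERSION, "dt": ds.dt,
                       "shape": {k: list(getattr(ds, k).shape)
                                 for k in ("z", "n", "y", "u")},
                       "provenance": ds.provenance}, fh, indent=2, default=str)


def read_dataset(path) -> NeuralDataset:
    with h5py.File(path, "r") as f:
        if "format_version" not in f.attrs:
            raise ValueError(f"{path}: not a ctdbench dataset "
                             "(missing format_version)")
        if int(f.attrs["format_version"]) != FORMAT_VERSION:
            raise ValueError(f"{path}: unsupported format version")
        data = f.get("data")
        missing = [k for k in ("z", "n", "y", "u")
                   if data is None or k not in data]
        if missing:
            raise ValueError(f"{path}: missing datasets {missing}")
        ds = NeuralDataset(
            z=f["data/z"][:], n=f["data/n"][:], y=f["data/y"][:],
            u=f["data/u"][:], dt=float(f.attrs["dt"]),
            provenance=json.loads(f.attrs["provenance"]))
        if "masks" in f:
            if "heldin" in f["masks"]:
                ds.heldin_mask = f["masks/heldin"][:].astype(bool)
            if "trial_split" in f["masks"]:
                ds.trial_split = f["masks/trial_split"][:]
    return ds
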