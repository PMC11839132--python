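"""Task environments: trial generation and objectives.

Two families of tasks are provided:

* **Flip-flop memory** (1-bit and 3-bit): each of ``n_bits`` noisy input
  channels occasionally emits a brief pulse of random sign; the target
  output on each channel is the sign of the most recent pulse.  A network
  solving the 3-bit version must maintain one of 8 discrete memory
  states.
* **Memory (Pro/Anti)**: a simplified two-task delayed-response set.  A
  stimulus angle is shown during a stimulus phase, withheld through a
  memory phase, and must be reported (MemoryPro) or reported flipped by
  180° (MemoryAnti) during the response phase, while a fixation output
  tracks a fixation input.

Trial generation is a pure function of ``(config, seed, n_trials)``:
identical arguments give byte-identical batches.  Targets are always
computed from the noiseless pulse/stimulus structure — input noise never
corrupts the target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

__all__ = [
    "EnvConfig", "TrialBatch", "gen_flipflop_trials", "gen_memory_trials",
    "task_loss", "FlipFlopEnv", "MEMORY_PRO", "MEMORY_ANTI",
]

MEMORY_PRO = "MemoryPro"
MEMORY_ANTI = "MemoryAnti"

# memory-task channel layout
_MEM_N_IN = 7      # 2 task cue + 4 sensory + 1 fixation
_MEM_N_OUT = 3     # fixation + (x, y)
PHASE_FIX, PHASE_STIM, PHASE_MEM, PHASE_RESP = 0, 1, 2, 3


@dataclass
class EnvConfig:
    """Parameters of a task environment.

    ``phase_lens`` applies to memory tasks only and must sum to
    ``trial_len``.  ``dt`` is a nominal bin width in seconds carried as
    metadata for firing-rate units; task time is abstract steps.
    """

    n_channels: int = 3
    trial_len: int = 500
    pulse_prob: float = 0.02
    pulse_amp: float = 1.0
    noise_sd: float = 0.05
    phase_lens: tuple = (20, 40, 60, 40)
    dt: float = 0.01
    seed: int = 0

    def validate(self, memory: bool = False):
        if self.trial_len < 1:
            raise ValueError("trial_len must be >= 1")
        if not 0.0 <= self.pulse_prob <= 1.0:
            raise ValueError("pulse_prob must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if memory and sum(self.phase_lens) != self.trial_len:
            raise ValueError(
                f"phase_lens {self.phase_lens} must sum to trial_len "
                f"{self.trial_len}")


@dataclass
class TrialBatch:
    """A batch of trials: inputs ``u``, targets ``x``, and trial metadata.

    ``pulses`` stores the noiseless pulse train for flip-flop tasks (zeros
    for memory tasks); it is what the targets are computed from and what
    downstream input-accuracy scoring transforms into "effective" inputs.
    """

    u: np.ndarray                 # [trials, time, d_u]
    x: np.ndarray                 # [trials, time, d_x]
    phase_labels: np.ndarray      # [trials, time] int
    task_id: np.ndarray           # [trials] int
    pulses: np.ndarray            # [trials, time, d_u] noiseless structure
    config: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.u.shape[:2] != self.x.shape[:2]:
            raise ValueError("u and x must share trial and time dimensions")

    @property
    def n_trials(self) -> int:
        return self.u.shape[0]

    @property
    def trial_len(self) -> int:
        return self.u.shape[1]

    # -- serialization --------------------------------------------------------
    def to_hdf5(self, path):
        with h5py.File(path, "w") as f:
            for name in ("u", "x", "phase_labels", "task_id", "pulses"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["config"] = json.dumps(self.config)
            f.attrs["seed"] = self.seed

    @classmethod
    def from_hdf5(cls, path) -> "TrialBatch":
        with h5py.File(path, "r") as f:
            return cls(
                u=f["u"][:], x=f["x"][:],
                phase_labels=f["phase_labels"][:], task_id=f["task_id"][:],
                pulses=f["pulses"][:],
                config=json.loads(f.attrs["config"]), seed=int(f.attrs["seed"]),
            )


def gen_flipflop_trials(cfg: EnvConfig, n_trials: int, n_bits: int = 3) -> TrialBatch:
    """Generate flip-flop trials.

    Each channel independently emits a pulse of amplitude ``±pulse_amp``
    (sign equiprobable) at Bernoulli(``pulse_prob``) steps; pulses are one
    step wide.  A forced pulse at t=0 sets the initial bit so the target
    is defined from the first step.  The target on channel c at step t is
    the sign of the most recent pulse on c at or before t.  Gaussian
    noise with sd ``noise_sd`` is added to the inputs only.
    """
    if n_bits not in (1, 3):
        raise ValueError("n_bits must be 1 or 3")
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    T, K = cfg.trial_len, n_bits

    mask = rng.random((n_trials, T, K)) < cfg.pulse_prob
    signs = rng.choice([-1.0, 1.0], size=(n_trials, T, K))
    pulses = np.where(mask, signs * cfg.pulse_amp, 0.0)
    # forced pulse at t=0 encodes the random initial bit state
    pulses[:, 0, :] = rng.choice([-1.0, 1.0], size=(n_trials, K)) * cfg.pulse_amp

    # target: sign of the most recent pulse (vectorized forward fill)
    sign_at_pulse = np.where(pulses != 0.0, np.sign(pulses), 0.0)
    idx = np.arange(T)[None, :, None]
    last = np.where(pulses != 0.0, idx, 0)
    last = np.maximum.accumulate(last, axis=1)
    x = np.take_along_axis(sign_at_pulse, last, axis=1)

    noise = rng.normal(scale=cfg.noise_sd, size=pulses.shape) if cfg.noise_sd > 0 \
        else np.zeros_like(pulses)
    u = pulses + noise

    return TrialBatch(
        u=u, x=x,
        phase_labels=np.zeros((n_trials, T), dtype=np.int64),
        task_id=np.zeros(n_trials, dtype=np.int64),
        pulses=pulses, config=json.loads(json.dumps(asdict(cfg))), seed=cfg.seed,
    )


def gen_memory_trials(cfg: EnvConfig, n_trials: int,
                      task_set=(MEMORY_PRO, MEMORY_ANTI)) -> TrialBatch:
    """Generate simplified MemoryPro/MemoryAnti trials.

    Input channels (7): one-hot task cue (2, constant over the trial),
    4 sensory channels of which the first two carry (cos θ, sin θ) during
    the stimulus phase only, and 1 fixation channel (1 during
    fixation/stimulus/memory, 0 during response).  Targets (3): fixation
    output mirroring the fixation input, then (x, y) equal to zero except
    during the response phase, when they encode θ (Pro) or θ+π (Anti).
    """
    task_set = tuple(task_set)
    if not task_set:
        raise ValueError("task_set must be non-empty")
    for t in task_set:
        if t not in (MEMORY_PRO, MEMORY_ANTI):
            raise ValueError(f"unknown task {t!r}")
    cfg.validate(memory=True)
    rng = np.random.default_rng(cfg.seed)
    T = cfg.trial_len
    lens = cfg.phase_lens
    bounds = np.cumsum((0,) + tuple(lens))
    phase_of_t = np.zeros(T, dtype=np.int64)
    for p in range(4):
        phase_of_t[bounds[p]:bounds[p + 1]] = p

    task_idx = rng.integers(0, len(task_set), size=n_trials)
    task_id = np.array(
        [0 if task_set[i] == MEMORY_PRO else 1 for i in task_idx], dtype=np.int64)
    theta = rng.uniform(0.0, 2 * np.pi, size=n_trials)

    clean = np.zeros((n_trials, T, _MEM_N_IN))
    clean[np.arange(n_trials), :, task_id] = 1.0                    # task cue
    stim = phase_of_t == PHASE_STIM
    clean[:, stim, 2] = np.cos(theta)[:, None]
    clean[:, stim, 3] = np.sin(theta)[:, None]
    clean[:, phase_of_t != PHASE_RESP, 6] = 1.0                     # fixation

    x = np.zeros((n_trials, T, _MEM_N_OUT))
    x[:, phase_of_t != PHASE_RESP, 0] = 1.0
    resp = phase_of_t == PHASE_RESP
    out_theta = np.where(task_id == 1, theta + np.pi, theta)
    x[:, resp, 1] = np.cos(out_theta)[:, None]
    x[:, resp, 2] = np.sin(out_theta)[:, None]

    noise = rng.normal(scale=cfg.noise_sd, size=clean.shape) if cfg.noise_sd > 0 \
        else np.zeros_like(clean)

    return TrialBatch(
        u=clean + noise, x=x,
        phase_labels=np.broadcast_to(phase_of_t, (n_trials, T)).copy(),
        task_id=task_id, pulses=np.zeros_like(clean),
        config=json.loads(json.dumps(asdict(cfg))), seed=cfg.seed,
    )


def task_loss(batch: TrialBatch, outputs: np.ndarray,
              response_weight: float = 1.0) -> float:
    """Mean squared error between outputs and targets.

    Averaged over trials, time and output dimensions.  For memory tasks a
    ``response_weight >= 1`` may up-weight response-phase steps; the loss
    is then a weighted mean so that weight 1 reduces to the plain MSE.
    """
    outputs = np.asarray(outputs)
    if outputs.shape != batch.x.shape:
        raise ValueError(
            f"outputs shape {outputs.shape} != targets shape {batch.x.shape}")
    if response_weight < 1.0:
        raise ValueError("response_weight must be >= 1")
    err = (outputs - batch.x) ** 2
    w = np.ones(batch.x.shape[:2])
    w[batch.phase_labels == PHASE_RESP] = response_weight
    return float((err * w[:, :, None]).sum() / (w.sum() * batch.x.shape[2]))


class FlipFlopEnv:
    """Reset/step interface over flip-flop trial generation.

    ``reset`` draws a fresh trial; ``step`` yields
    ``(observation, target, done)`` per time step.  This is the contract
    new tasks implement so the task trainer never needs task-specific
    code.
    """

    def __init__(self, cfg: EnvConfig, n_bits: int = 3):
        self.cfg = cfg
        self.n_bits = n_bits
        self._trial: TrialBatch | None = None
        self._t = 0
        self._count = 0

    def reset(self):
        cfg = EnvConfig(**{**asdict(self.cfg), "seed": self.cfg.seed + self._count})
        self._trial = gen_flipflop_trials(cfg, 1, self.n_bits)
        self._count += 1
        self._t = 0
        return self._trial.u[0, 0]

    def step(self):
        t = self._t
        self._t += 1
        done = self._t >= self.cfg.trial_len
        obs = self._trial.u[0, t]
        target = self._trial.x[0, t]
        return obs, target, done
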