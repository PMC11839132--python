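"""Small neural-network building blocks on the autodiff engine.

Shared by the data-driven models: linear layers, MLPs, GRU cells and a
bidirectional GRU sequence encoder.  Parameters are initialized with
uniform fan-in scaling from a caller-supplied generator so that every
model is reproducible from its seed.

The GRU keeps its three gate weight blocks fused into single matrices,
and input-side projections for a whole sequence are computed in one
matmul up front (``project_inputs``) — with a Python-loop tape, per-step
op count dominates the training cost.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, split_steps

__all__ = ["Linear", "MLP", "GRUCell", "BiGRUEncoder"]


def _uniform(rng, fan_in, shape):
    lim = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor.param(rng.uniform(-lim, lim, size=shape))


class Linear:
    def __init__(self, rng, d_in: int, d_out: int):
        self.W = _uniform(rng, d_in, (d_in, d_out))
        self.b = Tensor.param(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self):
        return [self.W, self.b]


class MLP:
    """tanh hidden layers, linear output."""

    def __init__(self, rng, dims: list[int]):
        self.layers = [Linear(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).tanh()
        return self.layers[-1](x)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class GRUCell:
    """Gated recurrent unit with fused gate weights.

    ``W`` stacks the input projections of the reset, update and
    candidate gates; ``U`` stacks the recurrent projections of reset and
    update (the candidate's recurrent path goes through ``Uc`` after the
    reset gate is applied).
    """

    def __init__(self, rng, d_in: int, d_hidden: int):
        H = d_hidden
        self.H = H
        self.W = _uniform(rng, d_in, (d_in, 3 * H))
        self.bx = Tensor.param(np.zeros(3 * H))
        self.U = _uniform(rng, H, (H, 2 * H))
        self.Uc = _uniform(rng, H, (H, H))

    def project_inputs(self, x) -> list[Tensor]:
        """One matmul for the input side of a whole [B, T, d] sequence."""
        x = x if isinstance(x, Tensor) else Tensor(x)
        B, T, d = x.shape
        flat = x.reshape(B * T, d) @ self.W + self.bx
        return split_steps(flat.reshape(B, T, 3 * self.H))

    def step(self, h: Tensor, xp: Tensor) -> Tensor:
        """Advance given a precomputed input projection xp = xW + b."""
        H = self.H
        hp = h @ self.U
        r = (xp[:, :H] + hp[:, :H]).sigmoid()
        z = (xp[:, H:2 * H] + hp[:, H:]).sigmoid()
        c = (xp[:, 2 * H:] + (r * h) @ self.Uc).tanh()
        return (1.0 - z) * h + z * c

    def __call__(self, h: Tensor, x: Tensor) -> Tensor:
        return self.step(h, x @ self.W + self.bx)

    def params(self):
        return [self.W, self.bx, self.U, self.Uc]


class BiGRUEncoder:
    """Bidirectional GRU over a [B, T, d] sequence; returns per-step
    features [B, 2*d_hidden] (a list over time) and the concatenated
    final states of both directions."""

    def __init__(self, rng, d_in: int, d_hidden: int):
        self.fwd = GRUCell(rng, d_in, d_hidden)
        self.bwd = GRUCell(rng, d_in, d_hidden)
        self.d_hidden = d_hidden

    def __call__(self, x):
        x = x if isinstance(x, Tensor) else Tensor(x)
        B = x.shape[0]
        xp_f = self.fwd.project_inputs(x)
        xp_b = self.bwd.project_inputs(x)
        h = Tensor(np.zeros((B, self.d_hidden)))
        fwd_states = []
        for xp in xp_f:
            h = self.fwd.step(h, xp)
            fwd_states.append(h)
        g = Tensor(np.zeros((B, self.d_hidden)))
        bwd_states = []
        for xp in reversed(xp_b):
            g = self.bwd.step(g, xp)
            bwd_states.append(g)
        bwd_states.reverse()
        feats = [concat([f, b], axis=-1) for f, b in zip(fwd_states, bwd_states)]
        final = concat([fwd_states[-1], bwd_states[0]], axis=-1)
        return feats, final

    def params(self):
        return self.fwd.params() + self.bwd.params()
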