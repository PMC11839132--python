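"""Input-conditioned fixed-point finding for discrete-time dynamics.

A fixed point of the state-update map ``F(z, u*)`` at a static input
``u*`` is a state with kinetic energy ``q(z) = ½‖F(z, u*) - z‖² ≈ 0``.
The finder runs gradient descent on q from a batch of initial states
(typically subsampled from observed trajectories), keeps converged
candidates, computes the Jacobian ``∂F/∂z`` at each, merges duplicates,
and labels stability: a discrete-time fixed point is stable iff every
Jacobian eigenvalue lies strictly inside the unit circle (for
continuous-time vector fields, pass ``stability_rule="continuous"`` to
use the Re(λ) < 0 rule on the flow Jacobian instead).

For a trained three-bit flip-flop network at zero input the expected
structure is 8 stable fixed points (the memory states, vertices of a
cube in state space) with unstable saddles between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Tensor, no_grad

__all__ = ["FixedPoint", "FPConfig", "find_fixed_points",
           "classify_and_dedupe", "sample_trajectory_states",
           "jacobian_fd", "fp_summary"]


@dataclass
class FPConfig:
    max_iters: int = 5000
    lr: float = 0.01
    q_tol: float = 1e-14         # per state dimension; Newton-refined FPs
                                 # reach machine precision, slow points do not
    merge_tol: float = 1e-2      # Euclidean, state units
    patience: int = 200          # stop if mean q stops improving
    newton_iters: int = 40       # quadratic refinement after descent
    newton_q_gate: float = 1e-3  # per-dim q below which refinement is tried
    seed: int = 0


@dataclass
class FixedPoint:
    z_star: np.ndarray
    u_star: np.ndarray
    q_value: float
    jacobian_eigs: np.ndarray | None = None
    stability: str | None = None          # "stable" | "unstable"
    n_merged: int = 1

    def __post_init__(self):
        if self.q_value < 0:
            raise ValueError("kinetic energy cannot be negative")


def sample_trajectory_states(z: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Subsample n states from a [trials, time, D] trajectory tensor."""
    flat = z.reshape(-1, z.shape[-1])
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(flat), size=min(n, len(flat)), replace=len(flat) < n)
    return flat[idx]


def jacobian_fd(dynamics, z_star: np.ndarray, u_star: np.ndarray,
                eps: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of the state map at z_star."""
    D = len(z_star)
    J = np.empty((D, D))
    with no_grad():
        for j in range(D):
            zp, zm = z_star.copy(), z_star.copy()
            zp[j] += eps
            zm[j] -= eps
            fp = dynamics(Tensor(zp[None]), Tensor(u_star[None])).data[0]
            fm = dynamics(Tensor(zm[None]), Tensor(u_star[None])).data[0]
            J[:, j] = (fp - fm) / (2 * eps)
    return J


def _batched_jacobian_fd(dynamics, Z: np.ndarray, U: np.ndarray,
                         eps: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobians for all rows of Z at once: [n, D, D]."""
    n, D = Z.shape
    J = np.empty((n, D, D))
    with no_grad():
        for j in range(D):
            Zp, Zm = Z.copy(), Z.copy()
            Zp[:, j] += eps
            Zm[:, j] -= eps
            fp = dynamics(Tensor(Zp), Tensor(U)).data
            fm = dynamics(Tensor(Zm), Tensor(U)).data
            J[:, :, j] = (fp - fm) / (2 * eps)
    return J


def _residual(dynamics, Z: np.ndarray, U: np.ndarray) -> np.ndarray:
    with no_grad():
        return dynamics(Tensor(Z), Tensor(U)).data - Z


def find_fixed_points(dynamics, u_star: np.ndarray, init_states: np.ndarray,
                      cfg: FPConfig | None = None) -> list[FixedPoint]:
    """Minimize kinetic energy from each initial state.

    ``dynamics(z, u)`` maps autodiff Tensors ``[batch, D] x [batch, d_u]``
    to the next state.  Two phases: batched Adam descent on q pulls each
    initialization into a slow region, then Newton iteration on
    ``F(z) - z = 0`` (gated on q already being small) collapses
    candidates onto exact fixed points so duplicates merge cleanly.
    Candidates with final ``q < q_tol * D`` are kept with their Jacobian
    spectrum; finding none returns an empty list (not an error).
    """
    cfg = cfg or FPConfig()
    u_star = np.asarray(u_star, dtype=np.float64)
    Z0 = np.asarray(init_states, dtype=np.float64)
    n, D = Z0.shape
    U = np.broadcast_to(u_star, (n, len(u_star))).copy()
    Zv = Tensor.param(Z0.copy())
    opt = Adam([Zv], lr=cfg.lr)
    tol = cfg.q_tol * D
    best_q = np.inf
    since_improve = 0
    for _ in range(cfg.max_iters):
        delta = dynamics(Zv, Tensor(U)) - Zv
        q = 0.5 * (delta**2).sum(axis=1)
        loss = q.sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
        qmean = float(q.data.mean())
        if qmean < best_q * (1 - 1e-4):
            best_q = qmean
            since_improve = 0
        else:
            since_improve += 1
        if float(q.data.max()) < tol or since_improve > cfg.patience:
            break

    Z = Zv.data
    delta = _residual(dynamics, Z, U)
    q = 0.5 * (delta**2).sum(axis=1)
    # Newton refinement: solve (J - I) step = -residual for candidates
    # already in a slow region; quadratic convergence onto the exact FP
    cand = np.flatnonzero(q < cfg.newton_q_gate * D)
    Zc, Uc = Z[cand].copy(), U[cand]
    qc = q[cand].copy()
    for _ in range(cfg.newton_iters):
        if len(Zc) == 0 or qc.max() < 1e-26 * D:
            break
        res = _residual(dynamics, Zc, Uc)
        J = _batched_jacobian_fd(dynamics, Zc, Uc)
        A = J - np.eye(D)[None]
        try:
            step = np.linalg.solve(A, -res[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack([np.linalg.lstsq(Ai, -ri, rcond=None)[0]
                             for Ai, ri in zip(A, res)])
        # per-candidate backtracking: accept the first scale that lowers q
        scale = np.ones((len(Zc), 1))
        accepted = np.zeros(len(Zc), dtype=bool)
        Z_next = Zc.copy()
        for _ in range(8):
            trial = Zc + scale * step
            r = _residual(dynamics, trial, Uc)
            q_trial = 0.5 * (r**2).sum(axis=1)
            better = (~accepted) & (q_trial < qc)
            Z_next[better] = trial[better]
            qc[better] = q_trial[better]
            accepted |= better
            if accepted.all():
                break
            scale[~accepted] *= 0.5
        Zc = Z_next
    if len(cand):
        improved = qc <= q[cand]
        Z[cand[improved]] = Zc[improved]
        q[cand[improved]] = qc[improved]

    out = []
    for i in np.flatnonzero(q < tol):
        z_star = Z[i].copy()
        Jm = jacobian_fd(dynamics, z_star, u_star)
        out.append(FixedPoint(z_star=z_star, u_star=u_star.copy(),
                              q_value=float(q[i]),
                              jacobian_eigs=np.linalg.eigvals(Jm)))
    return out


def classify_and_dedupe(fps: list[FixedPoint], merge_tol: float = 1e-2,
                        stability_rule: str = "discrete") -> list[FixedPoint]:
    """Greedy-merge duplicates and label stability.

    ``discrete``: stable iff all |λ| < 1 of the state-update Jacobian.
    ``continuous``: stable iff all Re(λ) < 0 of the flow Jacobian.
    Merged representatives keep the lowest-q member's location/spectrum
    and record how many candidates collapsed into them.
    """
    if stability_rule not in ("discrete", "continuous"):
        raise ValueError(f"unknown stability rule {stability_rule!r}")
    reps: list[FixedPoint] = []
    for fp in sorted(fps, key=lambda f: f.q_value):
        for rep in reps:
            if np.linalg.norm(fp.z_star - rep.z_star) < merge_tol:
                rep.n_merged += fp.n_merged
                break
        else:
            reps.append(FixedPoint(z_star=fp.z_star.copy(),
                                   u_star=fp.u_star.copy(),
                                   q_value=fp.q_value,
                                   jacobian_eigs=fp.jacobian_eigs.copy()
                                   if fp.jacobian_eigs is not None else None,
                                   n_merged=fp.n_merged))
    for rep in reps:
        if rep.jacobian_eigs is None:
            continue
        if stability_rule == "discrete":
            stable = bool(np.all(np.abs(rep.jacobian_eigs) < 1.0))
        else:
            stable = bool(np.all(rep.jacobian_eigs.real < 0.0))
        rep.stability = "stable" if stable else "unstable"
    return reps


def plot_fixed_points(fps: list[FixedPoint], z: np.ndarray, path):
    """Project fixed points and trajectories onto the top 2 PCs and save
    a figure (requires matplotlib; purely diagnostic)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    flat = z.reshape(-1, z.shape[-1])
    mu = flat.mean(axis=0)
    _, _, V = np.linalg.svd(flat - mu, full_matrices=False)
    P = V[:2].T
    fig, ax = plt.subplots(figsize=(5, 5))
    for trial in z[: min(len(z), 20)]:
        proj = (trial - mu) @ P
        ax.plot(proj[:, 0], proj[:, 1], color="0.7", lw=0.5, zorder=1)
    for fp in fps:
        proj = (fp.z_star - mu) @ P
        if fp.stability == "stable":
            ax.scatter(*proj, color="green", marker="o", zorder=2)
        else:
            ax.scatter(*proj, color="red", marker="x", zorder=2)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def fp_summary(fps: list[FixedPoint]) -> dict:
    """Counts and spectra, JSON-serializable."""
    return {
        "n_total": len(fps),
        "n_stable": sum(1 for f in fps if f.stability == "stable"),
        "n_unstable": sum(1 for f in fps if f.stability == "unstable"),
        "points": [{
            "z_star": f.z_star.tolist(),
            "u_star": f.u_star.tolist(),
            "q": f.q_value,
            "eigs_real": f.jacobian_eigs.real.tolist()
            if f.jacobian_eigs is not None else None,
            "eigs_imag": f.jacobian_eigs.imag.tolist()
            if f.jacobian_eigs is not None else None,
            "stability": f.stability,
            "n_merged": f.n_merged,
        } for f in fps],
    }
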