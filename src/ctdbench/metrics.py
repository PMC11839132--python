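"""Model-quality metrics for latent dynamics models.

Six metrics, grouped by what they need:

Ground-truth-requiring
    * ``rate_r2`` — variance-weighted R² between true and predicted
      firing rates (reconstruction).
    * ``state_r2`` — affine-map true latents into inferred-latent space,
      then variance-weighted R²; penalizes inferred structure the true
      system cannot explain, i.e. invented features (simplicity).
    * ``input_r2`` — affine-map inferred inputs into true-input space,
      then variance-weighted R² (input accuracy).

Ground-truth-free
    * ``co_bps`` — co-smoothing bits-per-spike: Poisson likelihood ratio
      (in bits, per spike) of held-out spikes under predicted rates vs.
      each neuron's mean rate (reconstruction).
    * ``cycle_consistency`` — can a thresholded linear map from inferred
      latents to inferred log-rates be inverted to regenerate the
      latents?  Latent dimensions living in the null space of the
      inferred embedding (invented features) cannot (simplicity).

Dynamics similarity
    * ``dsa_distance`` — delay-embed two trajectory sets, fit a linear
      one-step dynamics matrix to each, and compute the angular
      Procrustes-over-conjugation distance between the two matrices,
      minimized over the orthogonal group; 0 = identical dynamics,
      π/2 = maximally dissimilar.

All R²-type metrics use the same variance-weighted coefficient of
determination, so strongly modulated dimensions dominate and flat ones
cannot artificially deflate the score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["AffineFit", "MetricReport", "DSAConfig", "variance_weighted_r2",
           "affine_fit", "rate_r2", "state_r2", "input_r2", "co_bps",
           "cycle_consistency", "dsa_distance", "delay_embed",
           "fit_dynamics_matrix"]


# -- variance-weighted R² -----------------------------------------------------

def _flatten(a: np.ndarray) -> np.ndarray:
    """[..., d] -> [samples, d]."""
    a = np.asarray(a, dtype=np.float64)
    return a.reshape(-1, a.shape[-1])


def variance_weighted_r2(true, pred, weight_source=None) -> float:
    """Weighted mean over dimensions of per-dimension R².

    ``R²_i = 1 - SS_res_i / SS_tot_i`` with weights proportional to the
    variance of ``weight_source`` (default: ``true``) in each dimension.
    Zero-variance dimensions are excluded from both sums; if every
    dimension has zero variance the score is undefined.
    """
    t, p = _flatten(true), _flatten(pred)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch {t.shape} vs {p.shape}")
    w_src = t if weight_source is None else _flatten(weight_source)
    w = w_src.var(axis=0)
    keep = w > 0
    if not keep.any():
        raise ValueError("all dimensions have zero variance; R² undefined")
    t, p, w = t[:, keep], p[:, keep], w[keep]
    ss_res = ((t - p) ** 2).sum(axis=0)
    ss_tot = ((t - t.mean(axis=0)) ** 2).sum(axis=0)
    r2 = 1.0 - ss_res / ss_tot
    return float((w * r2).sum() / w.sum())


@dataclass
class AffineFit:
    """Least-squares affine map ``y ≈ x @ weights + intercept``."""

    weights: np.ndarray
    intercept: np.ndarray
    cond: float = float("nan")

    def predict(self, x: np.ndarray) -> np.ndarray:
        return _flatten(x) @ self.weights + self.intercept


def affine_fit(x, y, ridge: float = 1e-8) -> AffineFit:
    """Fit y ≈ xW + d by ridge-stabilized ordinary least squares.

    The ridge is scaled by ``trace(XᵀX)/d`` so it acts purely as
    conditioning, not regularization.
    """
    X, Y = _flatten(x), _flatten(y)
    n, d = X.shape
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} samples to fit affine map "
                         f"in {d} dims, got {n}")
    Xm, Ym = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - Xm, Y - Ym
    G = Xc.T @ Xc
    lam = ridge * np.trace(G) / max(d, 1)
    G_reg = G + lam * np.eye(d)
    W = np.linalg.solve(G_reg, Xc.T @ Yc)
    return AffineFit(weights=W, intercept=Ym - Xm @ W,
                     cond=float(np.linalg.cond(G_reg)))


# -- the three ground-truth metrics -------------------------------------------

def rate_r2(n: np.ndarray, n_hat: np.ndarray) -> float:
    """Variance-weighted R² of predicted vs. true firing rates."""
    return variance_weighted_r2(n, n_hat, weight_source=n)


def state_r2(z: np.ndarray, z_hat: np.ndarray) -> float:
    """Affine-map true latents to inferred latents, score in ẑ-space.

    Direction matters: inferred variance the true state cannot explain
    (invented features) lowers the score; true features the model missed
    do not.
    """
    fit = affine_fit(z, z_hat)
    return variance_weighted_r2(z_hat, fit.predict(z), weight_source=z_hat)


def input_r2(u: np.ndarray, u_hat: np.ndarray) -> float:
    """Affine-map inferred inputs to true inputs, score in u-space."""
    fit = affine_fit(u_hat, u)
    return variance_weighted_r2(u, fit.predict(u_hat), weight_source=u)


# -- co-smoothing bits-per-spike ----------------------------------------------

def co_bps(y_heldout: np.ndarray, n_hat_heldout: np.ndarray) -> float:
    """Poisson likelihood ratio per held-out spike, in bits.

    ``(LL(n̂; y) - LL(n̄; y)) / (y_sp · ln 2)`` where n̄_i is neuron i's
    mean rate over the evaluation set and y_sp the total held-out spike
    count.  Positive iff the predicted rates beat the mean-rate
    predictor; exactly 0 for the mean-rate predictor itself.
    """
    y = _flatten(y_heldout)
    lam = _flatten(n_hat_heldout)
    if y.shape != lam.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {lam.shape}")
    if (lam <= 0).any():
        raise ValueError("predicted rates must be strictly positive")
    y_sp = y.sum()
    if y_sp == 0:
        raise ValueError("no held-out spikes; co-bps undefined")
    lam_bar = np.maximum(y.mean(axis=0), 1e-12)
    ll_hat = (y * np.log(lam) - lam).sum()
    ll_bar = (y * np.log(lam_bar)).sum() - y.shape[0] * lam_bar.sum()
    return float((ll_hat - ll_bar) / (y_sp * np.log(2.0)))


# -- cycle-consistency --------------------------------------------------------

def cycle_consistency(z_hat: np.ndarray, n_hat: np.ndarray,
                      var_threshold: float = 0.01) -> float:
    """Simplicity score from inferred quantities alone.

    1. PCA-rotate centered inferred latents and inferred log-rates.
    2. Fit a linear map from rotated latents to rotated log-rates.
    3. Zero singular values of the map carrying less than
       ``var_threshold`` of the total squared-singular-value mass.
    4. Regenerate latents through the pseudo-inverse and return the
       variance-weighted R² between inferred and regenerated latents.

    Latent dimensions invisible to the (thresholded) embedding cannot be
    regenerated, so invented features directly reduce the score.
    """
    Z = _flatten(z_hat)
    L = np.log(_flatten(n_hat))
    n, d = Z.shape
    if n < d:
        raise ValueError(f"need at least {d} samples for {d} latent dims")
    Zc = Z - Z.mean(axis=0)
    Lc = L - L.mean(axis=0)
    # PCA rotations (full rank, just sorts dims by explained variance)
    _, _, Vz = np.linalg.svd(Zc, full_matrices=False)
    _, _, Vl = np.linalg.svd(Lc, full_matrices=False)
    Zp = Zc @ Vz.T
    Lp = Lc @ Vl.T
    W, *_ = np.linalg.lstsq(Zp, Lp, rcond=None)
    U, s, _ = np.linalg.svd(W, full_matrices=False)
    keep = s**2 >= var_threshold * (s**2).sum()
    # regenerate through the pseudo-inverse of the thresholded map:
    # Zp W_k pinv(W_k) projects onto the kept left-singular subspace
    Z_regen = Zp @ U[:, keep] @ U[:, keep].T
    w = Zp.var(axis=0)
    num = (w * ((Zp - Z_regen) ** 2).sum(axis=0)).sum()
    den = (w * (Zp ** 2).sum(axis=0)).sum()
    return float(1.0 - num / den)


# -- dynamical similarity analysis --------------------------------------------

@dataclass
class DSAConfig:
    n_delays: int = 10
    delay_stride: int = 1
    rank: int | None = None        # None = full rank
    n_iters: int = 300
    n_restarts: int = 5
    tol: float = 1e-13
    seed: int = 0

    def __post_init__(self):
        if self.n_delays < 1:
            raise ValueError("n_delays must be >= 1")


def delay_embed(traj: np.ndarray, n_delays: int, stride: int = 1) -> np.ndarray:
    """Stack ``n_delays`` lagged copies: [trials, T', d*n_delays]."""
    traj = np.asarray(traj, dtype=np.float64)
    if traj.ndim == 2:
        traj = traj[None]
    B, T, d = traj.shape
    span = (n_delays - 1) * stride
    if T - span < 2:
        raise ValueError(
            f"series of length {T} too short for {n_delays} delays "
            f"at stride {stride}")
    cols = [traj[:, k * stride: T - span + k * stride] for k in range(n_delays)]
    return np.concatenate(cols, axis=-1)


def fit_dynamics_matrix(traj: np.ndarray, cfg: DSAConfig) -> np.ndarray:
    """Least-squares one-step linear dynamics of the delay-embedded series."""
    emb = delay_embed(traj, cfg.n_delays, cfg.delay_stride)
    if cfg.rank is not None and cfg.rank < emb.shape[-1]:
        flat = emb.reshape(-1, emb.shape[-1])
        flat = flat - flat.mean(axis=0)
        _, _, V = np.linalg.svd(flat, full_matrices=False)
        emb = emb @ V[:cfg.rank].T
    X = emb[:, :-1].reshape(-1, emb.shape[-1])
    Y = emb[:, 1:].reshape(-1, emb.shape[-1])
    A, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return A.T   # convention: x_{t+1} = A x_t


def _polar_orthogonal(M: np.ndarray) -> np.ndarray:
    U, _, Vt = np.linalg.svd(M)
    return U @ Vt


def _align_orthogonal(Ax: np.ndarray, Ay: np.ndarray, cfg: DSAConfig) -> float:
    """max_{C in O(n)} <Ax, C Ay Cᵀ>_F.

    Projected gradient ascent (polar retraction) from several starts in
    both components of O(n), followed for small n by a quasi-Newton
    polish in the skew-symmetric tangent parametrization C·exp(S), which
    removes the slow terminal crawl of first-order ascent.
    """
    n = Ax.shape[0]
    rng = np.random.default_rng(cfg.seed)
    starts = [np.eye(n)]
    R = np.eye(n)
    R[0, 0] = -1.0
    starts.append(R)            # cover the reflection component of O(n)
    while len(starts) < cfg.n_restarts:
        Q = _polar_orthogonal(rng.normal(size=(n, n)))
        starts.append(Q)
    best = -np.inf
    endpoints = []
    for C in starts:
        C = C.copy()
        step = 1.0 / max(np.linalg.norm(Ay, "fro") ** 2, 1e-12)
        f_prev = float((Ax * (C @ Ay @ C.T)).sum())
        for _ in range(cfg.n_iters):
            G = Ax @ C @ Ay.T + Ax.T @ C @ Ay
            improved = False
            for _ in range(20):   # backtracking on the retracted step
                C_new = _polar_orthogonal(C + step * G)
                f_new = float((Ax * (C_new @ Ay @ C_new.T)).sum())
                if f_new > f_prev:
                    improved = True
                    break
                step *= 0.5
            if not improved:
                break
            C = C_new
            if f_new - f_prev < cfg.tol * max(abs(f_prev), 1.0):
                f_prev = f_new
                break
            f_prev = f_new
            step *= 1.5
        best = max(best, f_prev)
        endpoints.append(C)
    if n <= 16:
        from scipy.linalg import expm
        from scipy.optimize import minimize
        iu = np.triu_indices(n, 1)
        for C0 in endpoints:
            def neg_f(theta, C0=C0):
                S = np.zeros((n, n))
                S[iu] = theta
                S -= S.T
                Cp = C0 @ expm(S)
                return -float((Ax * (Cp @ Ay @ Cp.T)).sum())

            # the objective can be very flat near its maximum; default
            # gradient tolerances stop prematurely
            res = minimize(neg_f, np.zeros(len(iu[0])), method="L-BFGS-B",
                           options={"maxiter": 500, "gtol": 1e-12,
                                    "ftol": 1e-15})
            best = max(best, -float(res.fun))
    return best


def dsa_distance(traj_x: np.ndarray, traj_y: np.ndarray,
                 cfg: DSAConfig | None = None) -> float:
    """Angular dynamics-similarity distance in [0, π/2].

    Minimizes ``‖Ax - C Ay C⁻¹‖_F`` over orthogonal C (equivalently
    maximizes the Frobenius inner product, since conjugation by an
    orthogonal matrix preserves ‖Ay‖) and returns
    ``arccos(<Ax, C*Ay C*ᵀ> / (‖Ax‖ ‖Ay‖))``.
    """
    cfg = cfg or DSAConfig()
    Ax = fit_dynamics_matrix(traj_x, cfg)
    Ay = fit_dynamics_matrix(traj_y, cfg)
    nx, ny = np.linalg.norm(Ax, "fro"), np.linalg.norm(Ay, "fro")
    if nx < 1e-12 or ny < 1e-12:
        raise ValueError("degenerate (zero) dynamics matrix")
    if Ax.shape != Ay.shape:
        raise ValueError(f"dynamics matrices differ in size: "
                         f"{Ax.shape} vs {Ay.shape}")
    inner = _align_orthogonal(Ax, Ay, cfg)
    cosang = np.clip(inner / (nx * ny), -1.0, 1.0)
    return float(np.clip(np.arccos(cosang), 0.0, np.pi / 2))


# -- report container ---------------------------------------------------------

@dataclass
class MetricReport:
    """One row of metrics for a (model, dataset) pair."""

    rate_r2: float | None = None
    state_r2: float | None = None
    input_r2: float | None = None
    co_bps: float | None = None
    cycle_consistency: float | None = None
    dsa_distance: float | None = None
    diagnostics: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=str)

    def to_csv_row(self) -> dict:
        row = {k: v for k, v in asdict(self).items()
               if k not in ("diagnostics", "config")}
        row.update({f"cfg_{k}": v for k, v in self.config.items()})
        return row
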