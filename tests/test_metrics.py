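"""Metric oracles: loop-based, closed-form, and brute-force checks."""

import numpy as np
import pytest

from ctdbench.metrics import (DSAConfig, affine_fit, co_bps, cycle_consistency,
                              dsa_distance, delay_embed, fit_dynamics_matrix,
                              input_r2, rate_r2, state_r2,
                              variance_weighted_r2)
from ctdbench.metrics import _align_orthogonal


# -- variance-weighted R² -----------------------------------------------------

class TestVarianceWeightedR2:
    def test_matches_per_dimension_loop_oracle(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=(500, 3)) * [1.0, 2.0, 0.5]
        p = t + rng.normal(size=t.shape) * 0.3
        w_src = rng.normal(size=(500, 3)) * [3.0, 1.0, 0.2]
        num = den = 0.0
        for i in range(3):
            w = w_src[:, i].var()
            ss_res = ((t[:, i] - p[:, i]) ** 2).sum()
            ss_tot = ((t[:, i] - t[:, i].mean()) ** 2).sum()
            num += w * (1 - ss_res / ss_tot)
            den += w
        assert variance_weighted_r2(t, p, w_src) == \
            pytest.approx(num / den, abs=1e-12)

    def test_perfect_prediction_is_one(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=(50, 4, 3))
        assert variance_weighted_r2(t, t) == 1.0

    def test_mean_prediction_is_zero(self):
        rng = np.random.default_rng(2)
        t = rng.normal(size=(200, 3))
        p = np.broadcast_to(t.mean(axis=0), t.shape)
        assert variance_weighted_r2(t, p) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_dims_excluded(self):
        rng = np.random.default_rng(3)
        t = np.column_stack([rng.normal(size=100), np.full(100, 2.0)])
        p = np.column_stack([t[:, 0], rng.normal(size=100)])
        assert variance_weighted_r2(t, p) == pytest.approx(1.0)

    def test_all_flat_dims_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            variance_weighted_r2(np.ones((50, 2)), np.ones((50, 2)))


class TestRateR2:
    def test_exact_rates_give_one(self):
        rng = np.random.default_rng(4)
        n = np.exp(rng.normal(size=(20, 30, 5)))
        assert rate_r2(n, n) == 1.0

    def test_trial_shuffled_rates_score_at_most_zeroish(self):
        rng = np.random.default_rng(5)
        n = np.exp(rng.normal(size=(40, 20, 6)))
        perm = rng.permutation(40)
        assert rate_r2(n, n[perm]) < 0.1

    def test_doubling_a_neurons_variance_doubles_its_weight(self):
        rng = np.random.default_rng(6)
        t = rng.normal(size=(300, 2))
        p = t + rng.normal(size=t.shape)
        t2 = t.copy()
        t2[:, 1] = t[:, 1] * np.sqrt(2)   # doubles Var of dim 1
        # loop oracle with explicitly doubled weight
        w = t.var(axis=0) * [1.0, 2.0]
        r2 = []
        for i in range(2):
            tt = t2[:, i]
            ss_res = ((tt - p[:, i]) ** 2).sum()
            ss_tot = ((tt - tt.mean()) ** 2).sum()
            r2.append(1 - ss_res / ss_tot)
        expect = (w * r2).sum() / w.sum()
        assert rate_r2(t2, p) == pytest.approx(expect, abs=1e-12)


class TestStateR2:
    def test_full_rank_affine_transform_scores_one(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=(30, 40, 5))
        M = rng.normal(size=(5, 5)) + np.eye(5)
        z_hat = z @ M + rng.normal(size=5)
        assert state_r2(z, z_hat) == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_dim_lowers_score_by_analytic_amount(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=(5000, 2))
        for noise_sd in (0.5, 1.0, 2.0):
            q = rng.normal(size=(5000, 1)) * noise_sd
            z_hat = np.concatenate([z, q], axis=1)
            got = state_r2(z, z_hat)
            # analytic: noise dim has R² ~ 0, weight = its variance
            v = np.concatenate([z.var(axis=0), q.var(axis=0)])
            expect = (v[:2].sum()) / v.sum()
            assert got == pytest.approx(expect, abs=0.02)
        # monotone in the variance share of the invented dim
        scores = []
        for noise_sd in (0.5, 1.0, 2.0):
            q = rng.normal(size=(5000, 1)) * noise_sd
            scores.append(state_r2(z, np.concatenate([z, q], axis=1)))
        assert scores[0] > scores[1] > scores[2]

    def test_saturating_nonlinearity_scores_below_one(self):
        rng = np.random.default_rng(9)
        z = rng.normal(size=(3000, 3))
        assert state_r2(z, np.tanh(3 * z)) < 0.95

    def test_invariant_to_invertible_affine_transform_of_true_latents(self):
        rng = np.random.default_rng(10)
        z = rng.normal(size=(2000, 4))
        z_hat = np.tanh(z @ rng.normal(size=(4, 6)))
        M = rng.normal(size=(4, 4)) + 2 * np.eye(4)
        # conditioning ridge in the affine fit limits exactness slightly
        assert state_r2(z @ M + 1.0, z_hat) == \
            pytest.approx(state_r2(z, z_hat), abs=1e-4)


class TestInputR2:
    def test_permuted_scaled_inputs_score_one(self):
        rng = np.random.default_rng(11)
        u = rng.normal(size=(50, 30, 3))
        u_hat = u[..., [2, 0, 1]] * [-1.5, 0.3, 4.0] + 0.7
        assert input_r2(u, u_hat) == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_scores_near_zero(self):
        rng = np.random.default_rng(12)
        u = rng.normal(size=(40, 50, 3))
        u_hat = rng.normal(size=(40, 50, 3))
        assert abs(input_r2(u, u_hat)) < 0.01

    def test_zeroed_channel_gives_analytic_weighted_average(self):
        rng = np.random.default_rng(13)
        u = rng.normal(size=(8000, 3)) * [1.0, 2.0, 3.0]
        u_hat = u.copy()
        u_hat[:, 0] = 0.0
        v = u.var(axis=0)
        expect = v[1:].sum() / v.sum()   # channel 0 predicted at R² ~ 0
        assert input_r2(u, u_hat) == pytest.approx(expect, abs=0.01)


# -- co-smoothing bits-per-spike ----------------------------------------------

class TestCoBPS:
    def test_matches_hand_computed_single_neuron_two_bins(self):
        # y = [2, 0], n_hat = [1.5, 0.3]; mean rate = 1.0
        y = np.array([[[2], [0]]], dtype=float)
        n_hat = np.array([[[1.5], [0.3]]])
        ll_hat = 2 * np.log(1.5) - 1.5 + 0 * np.log(0.3) - 0.3
        ll_bar = 2 * np.log(1.0) - 1.0 + 0 * np.log(1.0) - 1.0
        expect = (ll_hat - ll_bar) / (2 * np.log(2))
        assert co_bps(y, n_hat) == pytest.approx(expect, abs=1e-12)

    def test_mean_rate_predictor_scores_exactly_zero(self):
        rng = np.random.default_rng(14)
        y = rng.poisson(0.4, size=(30, 20, 8)).astype(float)
        nbar = np.broadcast_to(y.reshape(-1, 8).mean(axis=0), y.shape)
        assert co_bps(y, np.maximum(nbar, 1e-12)) == pytest.approx(0.0, abs=1e-12)

    def test_true_rates_beat_mean_predictor(self):
        rng = np.random.default_rng(15)
        lam = np.exp(rng.normal(scale=0.8, size=(50, 40, 10))) * 0.2
        y = rng.poisson(lam).astype(float)
        assert co_bps(y, lam) > 0

    def test_invariant_to_neuron_permutation(self):
        rng = np.random.default_rng(16)
        lam = np.exp(rng.normal(size=(20, 30, 6))) * 0.3
        y = rng.poisson(lam).astype(float)
        perm = rng.permutation(6)
        assert co_bps(y[..., perm], lam[..., perm]) == \
            pytest.approx(co_bps(y, lam), abs=1e-12)

    def test_no_spikes_rejected(self):
        with pytest.raises(ValueError, match="no held-out spikes"):
            co_bps(np.zeros((5, 5, 2)), np.full((5, 5, 2), 0.1))


# -- cycle-consistency --------------------------------------------------------

class TestCycleConsistency:
    def test_full_rank_linear_embedding_scores_one(self):
        rng = np.random.default_rng(17)
        z = rng.normal(size=(3000, 4))
        W = rng.normal(size=(4, 12))
        n_hat = np.exp(z @ W + 0.2)
        assert cycle_consistency(z, n_hat) == pytest.approx(1.0, abs=1e-6)

    def test_null_space_dim_scores_analytic_value(self):
        # embedding reads only s; q is invented. With weights w_i = Var_i
        # of the PCA-rotated latents, the score is 1 - Vq²/(Vs² + Vq²).
        rng = np.random.default_rng(18)
        s = rng.normal(size=(20000, 1)) * 2.0
        q = rng.normal(size=(20000, 1)) * 1.2
        z_hat = np.concatenate([s, q], axis=1)
        n_hat = np.exp(np.concatenate([s, -0.5 * s, 0.25 * s], axis=1))
        vs, vq = s.var(), q.var()
        expect = 1 - vq**2 / (vs**2 + vq**2)
        assert cycle_consistency(z_hat, n_hat) == pytest.approx(expect, abs=0.01)

    def test_invariant_to_invertible_transform_when_embedding_injective(self):
        rng = np.random.default_rng(19)
        z = rng.normal(size=(4000, 3))
        # well-conditioned injective map: no singular value falls under
        # the 1% variance threshold
        W = np.diag([1.0, 0.8, 0.6]) @ np.linalg.qr(rng.normal(size=(9, 3)))[0].T
        n_hat = np.exp(z @ W * 0.5)
        Q1 = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        Q2 = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        M = Q1 @ np.diag([1.5, 1.0, 0.7]) @ Q2   # invertible, well-conditioned
        assert cycle_consistency(z, n_hat) == pytest.approx(1.0, abs=1e-6)
        assert cycle_consistency(z @ M, n_hat) == pytest.approx(1.0, abs=1e-6)

    def test_invariant_to_orthogonal_transform_of_latents(self):
        # with a non-injective embedding the score depends on the latent
        # basis only through PCA, so orthogonal transforms preserve it
        rng = np.random.default_rng(29)
        z = rng.normal(size=(4000, 3)) * [2.0, 1.0, 0.5]
        n_hat = np.exp(np.column_stack([z[:, 0], z[:, 1],
                                        z[:, 0] - z[:, 1]]) * 0.5)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        a = cycle_consistency(z, n_hat)
        b = cycle_consistency(z @ Q, n_hat)
        assert a == pytest.approx(b, abs=1e-6)

    def test_default_threshold_is_one_percent_of_variance(self):
        import inspect
        sig = inspect.signature(cycle_consistency)
        assert sig.parameters["var_threshold"].default == 0.01


# -- DSA ----------------------------------------------------------------------

def _rot(theta):
    return np.array([[np.cos(theta), -np.sin(theta)],
                     [np.sin(theta), np.cos(theta)]])


def _lin_traj(A, T=150, B=6, seed=0, noise=0.01):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(B, A.shape[0]))
    out = [x]
    for _ in range(T - 1):
        x = x @ A.T + noise * rng.normal(size=x.shape)
        out.append(x)
    return np.stack(out, axis=1)


class TestDSA:
    def test_self_distance_is_zero(self):
        rng = np.random.default_rng(20)
        traj = rng.normal(size=(5, 80, 3))
        assert dsa_distance(traj, traj) == pytest.approx(0.0, abs=1e-6)

    def test_invariant_to_orthogonal_conjugation(self):
        # rotating a trajectory conjugates its fitted dynamics matrix
        # exactly, so the aligned distance must vanish
        A = _rot(0.35) * 0.98
        rng = np.random.default_rng(21)
        Q, _ = np.linalg.qr(rng.normal(size=(2, 2)))
        tx = _lin_traj(A, seed=1)
        ty = tx @ Q.T
        cfg = DSAConfig(n_delays=1)
        assert dsa_distance(tx, ty, cfg) == pytest.approx(0.0, abs=1e-3)

    def test_symmetric_under_argument_swap(self):
        tx = _lin_traj(_rot(0.3) * 0.95, seed=3)
        ty = _lin_traj(_rot(0.9) * 0.95, seed=4)
        cfg = DSAConfig(n_delays=1)
        assert dsa_distance(tx, ty, cfg) == \
            pytest.approx(dsa_distance(ty, tx, cfg), abs=1e-3)

    def test_rotation_systems_match_O2_grid_search_oracle(self):
        # brute-force the alignment over a fine grid of O(2)
        for a, b in [(0.3, 0.8), (0.2, 1.2)]:
            Ax, Ay = _rot(a), _rot(b)
            best = -np.inf
            for ang in np.linspace(0, 2 * np.pi, 7201):
                for refl in (1.0, -1.0):
                    C = _rot(ang) @ np.diag([1.0, refl])
                    best = max(best, float((Ax * (C @ Ay @ C.T)).sum()))
            opt = _align_orthogonal(Ax, Ay, DSAConfig())
            d_opt = np.arccos(np.clip(opt / 2.0, -1, 1))   # ‖rot‖_F = √2
            d_grid = np.arccos(np.clip(best / 2.0, -1, 1))
            assert d_opt == pytest.approx(d_grid, abs=1e-3)

    def test_delay_embedding_shapes_and_content(self):
        traj = np.arange(24, dtype=float).reshape(1, 12, 2)
        emb = delay_embed(traj, n_delays=3, stride=2)
        assert emb.shape == (1, 8, 6)
        np.testing.assert_array_equal(emb[0, 0], traj[0, [0, 2, 4]].ravel())

    def test_degenerate_zero_dynamics_rejected(self):
        traj = np.zeros((3, 50, 2))
        traj[:, 0] = 1.0   # nonconstant but A fit is ~0
        with pytest.raises(ValueError, match="degenerate"):
            dsa_distance(traj, traj, DSAConfig(n_delays=1))

    def test_distance_lies_in_unit_interval_of_angles(self):
        rng = np.random.default_rng(22)
        tx = rng.normal(size=(4, 60, 2))
        ty = rng.normal(size=(4, 60, 2))
        d = dsa_distance(tx, ty)
        assert 0.0 <= d <= np.pi / 2


# -- affine fit ---------------------------------------------------------------

def test_affine_fit_recovers_exact_map():
    rng = np.random.default_rng(23)
    X = rng.normal(size=(500, 3))
    W = rng.normal(size=(3, 2))
    d = rng.normal(size=2)
    fit = affine_fit(X, X @ W + d)
    np.testing.assert_allclose(fit.weights, W, atol=1e-8)
    np.testing.assert_allclose(fit.intercept, d, atol=1e-8)


def test_affine_fit_needs_enough_samples():
    with pytest.raises(ValueError, match="samples"):
        affine_fit(np.ones((3, 5)), np.ones((3, 2)))


def test_dsa_rank_reduction_shrinks_dynamics_matrix():
    rng = np.random.default_rng(30)
    traj = rng.normal(size=(4, 60, 4))
    full = fit_dynamics_matrix(traj, DSAConfig(n_delays=3))
    red = fit_dynamics_matrix(traj, DSAConfig(n_delays=3, rank=5))
    assert full.shape == (12, 12)
    assert red.shape == (5, 5)


def test_metric_report_serializes_to_json_and_csv_row():
    import json
    from ctdbench.metrics import MetricReport
    rep = MetricReport(rate_r2=0.9, co_bps=0.2, config={"arch": "node-sae"})
    parsed = json.loads(rep.to_json())
    assert parsed["rate_r2"] == 0.9
    row = rep.to_csv_row()
    assert row["cfg_arch"] == "node-sae" and row["co_bps"] == 0.2


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), d=st.integers(1, 6),
       scale=st.floats(0.01, 10.0))
def test_r2_type_metrics_never_exceed_one(seed, d, scale):
    """Upper bound of every R²-style score, for arbitrary data."""
    rng = np.random.default_rng(seed)
    t = rng.normal(size=(200, d)) * scale
    p = rng.normal(size=(200, d))
    assert variance_weighted_r2(t, p) <= 1.0
    assert state_r2(t, p) <= 1.0 + 1e-12
    assert input_r2(t, p) <= 1.0 + 1e-12
    n_hat = np.exp(np.clip(p, -5, 5))
    assert cycle_consistency(t, n_hat) <= 1.0 + 1e-12
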