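"""GPFA: FA baseline, EM fitting, posterior inference, orthonormalization,
and leave-one-channel-out prediction error."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from hgstates import gpfa, synthetic
from hgstates.gpfa import GPFAParams


@pytest.fixture(scope="module")
def small_gpfa_data():
    """q=6, p=2 epochs from known parameters (quick EM exercises)."""
    rng = np.random.default_rng(0)
    C = rng.standard_normal((6, 2))
    C /= np.linalg.norm(C, axis=0)
    d = rng.uniform(-1, 1, 6)
    R = np.full(6, 0.2)
    taus = np.array([800.0, 4000.0])
    Y, X = synthetic.sample_gpfa_epochs(C, d, R, taus, n_epochs=20, T=60, seed=1)
    return C, d, R, taus, Y, X


class TestFABaseline:
    def test_recovers_loading_subspace(self, rng):
        C_true = rng.standard_normal((8, 2))
        z = rng.standard_normal((2, 6000))
        Y = (C_true @ z + 0.3 * rng.standard_normal((8, 6000))).reshape(8, 50, 120)
        fit = gpfa.fa_fit(Y.transpose(1, 0, 2), p=2)
        angle = np.degrees(subspace_angles(fit.C, C_true)).max()
        assert angle < 10.0

    def test_p_zero_gives_pure_noise_model(self, rng):
        Y = rng.standard_normal((5, 4, 30)) * np.array([1.0, 2.0, 3.0, 4.0])[None, :, None]
        fit = gpfa.fa_fit(Y, p=0)
        assert fit.C.shape == (4, 0)
        pooled = Y.transpose(0, 2, 1).reshape(-1, 4)
        assert np.allclose(fit.R, pooled.var(axis=0))

    def test_zero_smoothing_is_identity(self, rng):
        Y = rng.standard_normal((4, 5, 40))
        a = gpfa.fa_fit(Y, p=2, pre_smooth_ms=0)
        b = gpfa.fa_fit(Y, p=2)
        assert np.allclose(a.C, b.C)

    def test_smoothing_changes_fit(self, rng):
        Y = rng.standard_normal((4, 5, 40))
        a = gpfa.fa_fit(Y, p=2, pre_smooth_ms=1000.0)
        b = gpfa.fa_fit(Y, p=2)
        assert not np.allclose(a.C, b.C)

    def test_p_not_below_q_rejected(self, rng):
        with pytest.raises(ValueError):
            gpfa.fa_fit(rng.standard_normal((4, 3, 20)), p=3)


class TestPosterior:
    def test_matches_brute_force_conditioning_small_cases(self, rng):
        from hgstates.experiments import _explicit_gpfa_posterior

        for q, p, T in ((2, 1, 3), (3, 2, 8), (5, 3, 15)):
            C = rng.standard_normal((q, p))
            params = GPFAParams(C, rng.standard_normal(q), rng.uniform(0.1, 0.5, q),
                                rng.uniform(300, 4000, p))
            Y = rng.standard_normal((q, T))
            fast = gpfa.gpfa_posterior(params, Y)
            assert np.abs(fast - _explicit_gpfa_posterior(params, Y)).max() < 1e-8

    def test_uninformative_data_shrinks_to_prior_mean(self, rng):
        params = GPFAParams(
            rng.standard_normal((4, 2)), np.zeros(4), np.full(4, 1e12),
            np.array([500.0, 2000.0]),
        )
        x = gpfa.gpfa_posterior(params, rng.standard_normal((4, 10)))
        assert np.abs(x).max() < 1e-6

    def test_noiseless_orthogonal_loading_recovers_latents(self):
        # pseudo-inverse oracle: tiny R, huge tau, y = C x + d exactly
        rng = np.random.default_rng(5)
        C, _ = np.linalg.qr(rng.standard_normal((6, 2)))
        d = rng.standard_normal(6)
        T = 20
        x_true = np.tile(rng.standard_normal((2, 1)), (1, T))  # constant path
        params = GPFAParams(C, d, np.full(6, 1e-8), np.array([1e8, 1e8]))
        post = gpfa.gpfa_posterior(params, C @ x_true + d[:, None])
        assert np.allclose(post, x_true, atol=1e-3)

    def test_loglik_matches_explicit_gaussian(self, rng):
        from scipy.stats import multivariate_normal

        q, p, T = 3, 2, 5
        C = rng.standard_normal((q, p))
        d = rng.standard_normal(q)
        R = rng.uniform(0.2, 0.6, q)
        taus = np.array([700.0, 2500.0])
        params = GPFAParams(C, d, R, taus)
        Y = rng.standard_normal((q, T))
        Kbig = np.zeros((p * T, p * T))
        for i, tau in enumerate(taus):
            Kbig[i * T:(i + 1) * T, i * T:(i + 1) * T] = synthetic.gp_kernel(tau, T)
        Cbar = np.zeros((q * T, p * T))
        for t in range(T):
            for j in range(q):
                for i in range(p):
                    Cbar[t * q + j, i * T + t] = C[j, i]
        Syy = Cbar @ Kbig @ Cbar.T + np.diag(np.tile(R, T))
        ll_ref = multivariate_normal.logpdf(Y.T.reshape(-1), np.tile(d, T), Syy)
        assert gpfa.loglik(params, Y[None]) == pytest.approx(ll_ref, abs=1e-8)


class TestEM:
    def test_loglik_monotone_nondecreasing(self, small_gpfa_data):
        *_, Y, _ = small_gpfa_data
        fit = gpfa.gpfa_fit_em(Y, p=2, max_iter=30, tol=0.0)
        gains = np.diff(fit.fit_log)
        assert np.all(gains >= -1e-6 * np.abs(fit.fit_log[:-1]))

    def test_white_latent_limit_matches_fa_loglik(self, rng):
        # on temporally white data, GPFA with tiny fixed taus is FA
        Y = rng.standard_normal((15, 5, 40)) + 2.0
        fa = gpfa.fa_fit(Y, p=2, seed=0)
        gp = gpfa.gpfa_fit_em(
            Y, p=2, max_iter=40, tol=1e-8, seed=0,
            taus_init=np.array([1.0, 1.0]), fit_taus=False,
        )
        ll_fa = gpfa.loglik(GPFAParams(fa.C, fa.d, fa.R, None), Y)
        ll_gp = gpfa.loglik(gp, Y)
        assert ll_gp == pytest.approx(ll_fa, rel=0.01)

    def test_r_floor_and_tau_clamps_respected(self, small_gpfa_data):
        *_, Y, _ = small_gpfa_data
        fit = gpfa.gpfa_fit_em(Y, p=2, max_iter=15, tol=1e-8)
        assert np.all(fit.R > 0)
        assert np.all(fit.taus_ms >= gpfa.BIN_MS / 2)


class TestOrthonormalize:
    def test_orthogonal_loading_with_distinct_norms_rescales_only(self, rng):
        # columns already orthogonal with distinct norms: U matches the
        # normalized columns and paths are just scaled, both up to sign
        U0, _ = np.linalg.qr(rng.standard_normal((5, 2)))
        D0 = np.array([2.0, 1.0])
        C = U0 * D0
        params = GPFAParams(C, np.zeros(5), np.ones(5), np.array([500.0, 1000.0]))
        trajs = gpfa.LatentTrajectories(rng.standard_normal((3, 2, 7)))
        out = gpfa.orthonormalize(params, trajs)
        assert np.allclose(np.abs(out.U.T @ U0), np.eye(2), atol=1e-10)
        assert np.allclose(np.abs(out.paths), np.abs(D0[None, :, None] * trajs.paths), atol=1e-10)
        assert np.allclose(out.D_diag, D0)

    def test_reconstruction_identity(self, rng):
        C = rng.standard_normal((6, 3))
        params = GPFAParams(C, np.zeros(6), np.ones(6), np.array([500.0, 1000.0, 2000.0]))
        trajs = gpfa.LatentTrajectories(rng.standard_normal((4, 3, 9)))
        out = gpfa.orthonormalize(params, trajs)
        recon = np.einsum("qp,ept->eqt", out.U, out.paths)
        direct = np.einsum("qp,ept->eqt", C, trajs.paths)
        assert np.abs(recon - direct).max() < 1e-10

    def test_factor_variance_ordered_by_singular_value(self, small_gpfa_data):
        *_, Y, _ = small_gpfa_data
        fit = gpfa.gpfa_fit_em(Y, p=2, max_iter=30, tol=1e-6)
        trajs = gpfa.infer_latents(fit, Y)
        out = gpfa.orthonormalize(fit, trajs)
        variances = out.paths.var(axis=(0, 2))
        assert np.all(np.diff(variances) <= 1e-9)
        assert np.all(np.diff(out.D_diag) <= 1e-12)

    def test_rank_deficient_loading_drops_factors(self, rng):
        c1 = rng.standard_normal((5, 1))
        C = np.concatenate([c1, c1], axis=1)  # rank 1
        params = GPFAParams(C, np.zeros(5), np.ones(5), np.array([500.0, 1000.0]))
        trajs = gpfa.LatentTrajectories(rng.standard_normal((2, 2, 6)))
        with pytest.warns(UserWarning, match="rank-deficient"):
            out = gpfa.orthonormalize(params, trajs)
        assert out.U.shape == (5, 1)


class TestLOORMSE:
    def test_noiseless_rank_p_data_near_zero_error(self, rng):
        C, _ = np.linalg.qr(rng.standard_normal((6, 2)))
        x = np.tile(rng.standard_normal((2, 1)), (1, 30))
        Y = np.stack([C @ x for _ in range(4)])
        params = GPFAParams(C, np.zeros(6), np.full(6, 1e-8), np.array([1e8, 1e8]))
        rmse = gpfa.loo_rmse(params, Y, np.array(["a"] * 4))
        assert rmse < 1e-2

    def test_class_balanced_sum_over_classes(self, small_gpfa_data):
        C, d, R, taus, Y, _ = small_gpfa_data
        params = GPFAParams(C, d, R, taus)
        labels_one = np.array(["a"] * Y.shape[0])
        labels_two = np.array(["a", "b"] * (Y.shape[0] // 2))
        one = gpfa.loo_rmse(params, Y, labels_one)
        two = gpfa.loo_rmse(params, Y, labels_two)
        # two classes of identical statistics: summed RMSE roughly doubles
        assert two == pytest.approx(2 * one, rel=0.1)

    def test_reduced_at_full_rank_equals_plain_prediction(self, small_gpfa_data):
        C, d, R, taus, Y, _ = small_gpfa_data
        params = GPFAParams(C, d, R, taus)
        labels = np.array(["a"] * Y.shape[0])
        assert gpfa.loo_rmse(params, Y, labels, reduced_m=2) == pytest.approx(
            gpfa.loo_rmse(params, Y, labels), abs=1e-10
        )


class TestFoldLatents:
    def test_factors_sorted_slowest_first_and_curves_meet(self, small_gpfa_data):
        *_, Y, _ = small_gpfa_data
        labels = np.array(["a", "b"] * (Y.shape[0] // 2))
        from hgstates import validation

        plan = validation.make_cv_plan(Y.shape[0], k=4)
        folds = gpfa.fit_fold_latents(Y, labels, plan, p=2, seed=0, max_iter=20)
        for fl in folds:
            assert np.all(np.diff(fl.taus_ms) <= 0)
        slow = gpfa.factor_decoding_curve(folds, labels, "slow_first")
        fast = gpfa.factor_decoding_curve(folds, labels, "fast_first")
        assert np.allclose(slow.per_fold[:, -1], fast.per_fold[:, -1])

    def test_single_factor_outputs_rank_aligned(self, small_gpfa_data):
        *_, Y, _ = small_gpfa_data
        labels = np.array(["a", "b"] * (Y.shape[0] // 2))
        from hgstates import validation

        plan = validation.make_cv_plan(Y.shape[0], k=4)
        folds = gpfa.fit_fold_latents(Y, labels, plan, p=2, seed=0, max_iter=20)
        taus, accs = gpfa.single_factor_decoding(folds, labels)
        assert taus.shape == accs.shape == (2,)
        assert taus[0] >= taus[1]
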