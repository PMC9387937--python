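"""Generator: GP latents match their kernel, planted statistics are realized,
and generation is reproducible."""

import numpy as np
import pytest

from hgstates import preprocess, synthetic


class TestGPLatents:
    def test_kernel_lag1_autocorrelation_matches_closed_form(self):
        # closed-form oracle: corr(x_t, x_{t+1}) = (1 - s_n^2) exp(-dt^2 / 2 tau^2)
        tau, bin_ms = 1000.0, 250.0
        expected = (1 - synthetic.SIGMA_N_SQ) * np.exp(-(bin_ms**2) / (2 * tau**2))
        x = synthetic.sample_gp_latents([tau] * 50, T=200, bin_ms=bin_ms, seed=3)
        a, b = x[:, :-1].ravel(), x[:, 1:].ravel()
        emp = np.corrcoef(a, b)[0, 1]
        assert emp == pytest.approx(expected, abs=0.01)
        assert expected == pytest.approx(0.9683, abs=1e-3)

    def test_fully_correlated_limit_is_nearly_constant(self):
        x = synthetic.sample_gp_latents([1e9], T=100, seed=0)
        # residual wiggle is set by the kernel noise floor: var(diff) ~ 2 s_n^2
        assert np.var(np.diff(x[0])) < 5 * synthetic.SIGMA_N_SQ

    def test_white_limit_has_no_lag1_correlation(self):
        x = synthetic.sample_gp_latents([1e-3] * 40, T=100, seed=1)
        emp = np.corrcoef(x[:, :-1].ravel(), x[:, 1:].ravel())[0, 1]
        assert abs(emp) < 0.05

    def test_unit_marginal_variance(self):
        x = synthetic.sample_gp_latents([500.0] * 100, T=100, seed=5)
        assert np.var(x) == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("bad", [{"taus_ms": [-1.0]}, {"taus_ms": [0.0]}, {"bin_ms": 0.0}])
    def test_invalid_parameters_raise(self, bad):
        kwargs = {"taus_ms": [500.0], "T": 10, "bin_ms": 250.0, "seed": 0}
        kwargs.update(bad)
        with pytest.raises(ValueError):
            synthetic.sample_gp_latents(kwargs["taus_ms"], kwargs["T"], kwargs["bin_ms"])


class TestEnvelopeDataset:
    def test_pure_noise_state_has_planted_mean_and_identity_covariance(self):
        spec = synthetic.StateSpec(
            "noise",
            channel_mean=np.full(4, 5.0),
            channel_sd=np.ones(4),
            loading=np.ones((4, 1)),
            taus_ms=np.array([1000.0]),
            factor_scale=np.array([0.0]),  # factor silenced: pure noise
        )
        env, _, _ = synthetic.generate_envelope_dataset(
            [spec], synthetic.Schedule([("noise", 1500.0)]), seed=2
        )
        assert env.values.mean(axis=1) == pytest.approx(np.full(4, 5.0), abs=0.1)
        cov = np.cov(env.values)
        assert cov == pytest.approx(np.eye(4), abs=0.12)

    def test_loading_sign_flip_flips_channel_correlation(self, signflip_dataset):
        env, blocks, _ = signflip_dataset
        fs = env.fs_hz
        for _, row in blocks.iterrows():
            seg = env.values[:, int(row.start_s * fs) : int(row.end_s * fs)]
            r = np.corrcoef(seg)[0, 1]
            assert (r > 0.3) if row.state == "pos" else (r < -0.3)

    def test_per_state_moments_converge_to_spec(self):
        specs = synthetic.demo_state_specs(q=6)
        sched = synthetic.Schedule.repeated([s.name for s in specs], 2, block_len_s=600.0)
        env, blocks, gt = synthetic.generate_envelope_dataset(specs, sched, seed=9)
        for spec in specs:
            mask = gt.state_of_bin == spec.name
            block = env.values[:, mask]
            n = mask.sum()
            # 3-standard-error bands; bins are autocorrelated (slow factors),
            # so inflate the nominal SE by an effective-sample-size factor
            n_eff = n / 40
            target_cov = spec.planted_cov()
            sd = np.sqrt(np.diag(target_cov))
            assert block.mean(axis=1) == pytest.approx(
                spec.channel_mean, abs=float(3 * sd.max() / np.sqrt(n_eff))
            )
            emp_cov = np.cov(block)
            assert emp_cov == pytest.approx(
                target_cov, abs=float(3 * target_cov.max() / np.sqrt(n_eff))
            )

    def test_slow_factor_concentrates_envelope_power_at_low_frequency(self):
        # oracle: a tau = 2000 ms GP has most of its power below ~0.25 Hz,
        # a white envelope does not
        from scipy.signal import welch

        def make(tau_scale):
            taus, scales = tau_scale
            return synthetic.StateSpec(
                "s", np.zeros(2), np.ones(2), np.ones((2, 1)) / np.sqrt(2),
                np.array([taus]), np.array([scales]),
            )

        sched = synthetic.Schedule([("s", 1200.0)])
        env_slow, _, _ = synthetic.generate_envelope_dataset([make((2000.0, 3.0))], sched, seed=4)
        env_white, _, _ = synthetic.generate_envelope_dataset([make((2000.0, 0.0))], sched, seed=4)

        def low_frac(env):
            f, p = welch(env.values[0], fs=env.fs_hz, nperseg=256)
            return p[f < 0.25].sum() / p.sum()

        assert low_frac(env_slow) > 2 * low_frac(env_white)

    def test_mismatched_channel_counts_raise(self):
        s1 = synthetic.demo_state_specs(q=6)[0]
        s2 = synthetic.demo_state_specs(q=8)[1]
        with pytest.raises(ValueError, match="channel count"):
            synthetic.generate_envelope_dataset(
                [s1, s2], synthetic.Schedule([(s1.name, 300.0), (s2.name, 300.0)]), seed=0
            )

    def test_identical_seeds_bit_identical_different_seeds_differ(self):
        specs = synthetic.demo_state_specs(q=4)
        sched = synthetic.Schedule.repeated([s.name for s in specs], 1, block_len_s=60.0)
        a, _, _ = synthetic.generate_envelope_dataset(specs, sched, seed=11)
        b, _, _ = synthetic.generate_envelope_dataset(specs, sched, seed=11)
        c, _, _ = synthetic.generate_envelope_dataset(specs, sched, seed=12)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)


class TestStateSpecValidation:
    def test_all_zero_loading_column_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            synthetic.StateSpec(
                "bad", np.zeros(2), np.ones(2), np.zeros((2, 1)),
                np.array([100.0]), np.array([1.0]),
            )

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            synthetic.StateSpec(
                "bad", np.zeros(2), np.array([1.0, 0.0]), np.ones((2, 1)),
                np.array([100.0]), np.array([1.0]),
            )


class TestRawSynthesis:
    def test_constant_envelope_zero_noise_recovers_scaled_constant(self):
        # the stochastic band-limited carrier contributes ~16% per-bin Rayleigh
        # noise even with a constant modulator, so the recovered constant is
        # assessed on per-channel bin means, with the per-bin scatter checked
        # against that carrier noise figure
        env = preprocess.EnvelopeSeries(np.full((2, 400), 3.0), channel_ids=["a", "b"])
        raw = synthetic.generate_raw_recording(
            env, 512.0, seed=1, noise=synthetic.NoiseConfig.none()
        )
        rec = preprocess.extract_envelope(raw)
        k = rec.values.mean() / 3.0
        assert rec.values.mean(axis=1) == pytest.approx(np.full(2, 3.0 * k), rel=0.05)
        rel_sd = rec.values.std(axis=1) / rec.values.mean(axis=1)
        assert rel_sd == pytest.approx(np.full(2, 0.16), abs=0.05)

    def test_line_noise_only_vanishes_after_notch(self):
        env = preprocess.EnvelopeSeries(np.zeros((1, 40)) + 1e-9)
        raw = synthetic.generate_raw_recording(
            env, 512.0, seed=2,
            noise=synthetic.NoiseConfig(pink_rel=0.0, line_rel=1.0, spike_rate_hz=0.0),
        )
        # line amplitude is relative to the (near-zero) median envelope, so
        # inject the tone explicitly at a visible amplitude instead
        t = np.arange(raw.n_samples) / raw.fs_hz
        raw.samples[0] = 5.0 * np.sin(2 * np.pi * 60.0 * t)
        rec = preprocess.extract_envelope(preprocess.notch_filter(raw))
        assert np.median(rec.values) < 0.05

    def test_sinusoidal_envelope_dominates_psd_at_modulation_frequency(self):
        from scipy.signal import welch

        T = 480  # 120 s
        tt = (np.arange(T) + 0.5) * 0.25
        env = preprocess.EnvelopeSeries(5.0 + 2.0 * np.sin(2 * np.pi * 0.1 * tt)[None, :])
        raw = synthetic.generate_raw_recording(env, 512.0, seed=3)
        rec = preprocess.extract_envelope(raw)
        f, p = welch(rec.values[0] - rec.values[0].mean(), fs=4.0, nperseg=256)
        assert abs(f[np.argmax(p)] - 0.1) < 0.02

    def test_sub_nyquist_sampling_rate_rejected(self):
        env = preprocess.EnvelopeSeries(np.ones((1, 8)))
        with pytest.raises(ValueError, match="Nyquist"):
            synthetic.generate_raw_recording(env, 200.0)
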