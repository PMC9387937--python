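"""Conditioning chain: rejection, referencing, filters, envelope, despiking,
z-scoring."""

import numpy as np
import pytest

from hgstates import preprocess
from hgstates.preprocess import EnvelopeSeries, RawRecording


def tone(freq, fs=512.0, dur_s=20.0, q=3, amp=1.0):
    t = np.arange(int(fs * dur_s)) / fs
    return RawRecording(np.tile(amp * np.sin(2 * np.pi * freq * t), (q, 1)), fs,
                        [f"c{i}" for i in range(q)])


class TestRejectChannels:
    def test_identical_channels_all_kept(self, rng):
        x = rng.standard_normal(1000)
        raw = RawRecording(np.tile(x, (5, 1)), 512.0, list("abcde"))
        mask = preprocess.reject_channels(raw, "ecog")
        assert mask.keep.all()

    def test_single_high_power_channel_rejected(self, rng):
        # oracle: direct mean/SD arithmetic on mean squared values
        x = rng.standard_normal((11, 2000))
        x[7] *= 10.0  # 100x power
        raw = RawRecording(x, 512.0, [f"c{i}" for i in range(11)])
        power = np.mean(x**2, axis=1)
        expect = power <= power.mean() + 3 * power.std()
        assert not expect[7]
        mask = preprocess.reject_channels(raw, "ecog")
        assert np.array_equal(mask.keep, expect)
        assert mask.reason["c7"] == "power"

    def test_seeg_uses_tighter_threshold(self, rng):
        x = rng.standard_normal((11, 2000))
        x[4] *= 2.0
        raw = RawRecording(x, 2000.0, [f"c{i}" for i in range(11)], modality="seeg")
        power = np.mean(x**2, axis=1)
        expect = power <= power.mean() + 1.5 * power.std()
        assert np.array_equal(preprocess.reject_channels(raw).keep, expect)

    def test_exact_zero_sample_rejected_with_zeros_reason(self, rng):
        x = rng.standard_normal((4, 500)) + 5.0
        x[2, 123] = 0.0
        raw = RawRecording(x, 512.0, list("abcd"))
        mask = preprocess.reject_channels(raw, "ecog")
        assert not mask.keep[2]
        assert mask.reason["c"] == "zeros"

    def test_all_rejected_is_hard_error(self):
        raw = RawRecording(np.zeros((3, 100)), 512.0, list("abc"))
        with pytest.raises(RuntimeError):
            preprocess.reject_channels(raw, "ecog")


class TestRereference:
    def test_common_signal_cancels_under_common_average(self, rng):
        s = rng.standard_normal(1000)
        raw = RawRecording(np.tile(s, (4, 1)), 512.0, list("abcd"))
        out = preprocess.rereference(raw, "common_average")
        assert np.abs(out.samples).max() < 1e-12

    def test_bipolar_is_adjacent_difference(self, rng):
        a, b = rng.standard_normal((2, 100))
        raw = RawRecording(np.stack([a, b]), 512.0, ["A1", "A2"], modality="seeg")
        out = preprocess.rereference(raw, "bipolar_pairs")
        assert out.channel_ids == ["A1-A2"]
        assert np.allclose(out.samples[0], a - b)

    def test_three_contact_shank_gives_two_pairs(self, rng):
        raw = RawRecording(rng.standard_normal((5, 100)), 512.0,
                           ["A1", "A2", "A3", "B1", "B2"], modality="seeg")
        out = preprocess.rereference(raw, "bipolar_pairs")
        assert out.channel_ids == ["A1-A2", "A2-A3", "B1-B2"]

    def test_unparseable_channel_ids_raise(self, rng):
        raw = RawRecording(rng.standard_normal((3, 50)), 512.0, ["1", "2", "3"])
        with pytest.raises(ValueError):
            preprocess.rereference(raw, "bipolar_pairs")


class TestFilters:
    def test_notch_attenuates_60hz_by_30db(self):
        raw = tone(60.0, dur_s=60.0)
        out = preprocess.notch_filter(raw)
        sl = slice(512 * 5, 512 * 55)  # steady state, away from edge transients
        ratio = np.std(out.samples[0][sl]) / np.std(raw.samples[0][sl])
        assert ratio < 0.032

    def test_notch_passes_90hz(self):
        raw = tone(90.0, dur_s=60.0)
        out = preprocess.notch_filter(raw)
        sl = slice(512 * 5, 512 * 55)
        ratio = np.std(out.samples[0][sl]) / np.std(raw.samples[0][sl])
        assert abs(1 - ratio) < 0.12

    def test_notch_preserves_dc(self):
        raw = RawRecording(np.full((3, 5000), 2.5), 512.0, list("abc"))
        out = preprocess.notch_filter(raw)
        assert np.allclose(out.samples, 2.5, atol=1e-6)

    def test_notch_skips_centers_above_nyquist(self):
        raw = tone(30.0, fs=256.0)
        out = preprocess.notch_filter(raw)  # 180/240 Hz > Nyquist: skipped
        assert out.samples.shape == raw.samples.shape

    def test_downsample_preserves_passband_tone(self):
        raw = tone(100.0, fs=2000.0, dur_s=10.0)
        out = preprocess.downsample(raw, 500.0)
        assert out.fs_hz == 500.0
        assert out.n_samples == raw.n_samples // 4
        sl = slice(500, 4500)
        assert np.std(out.samples[0][sl]) == pytest.approx(np.std(raw.samples[0][sl]), rel=0.02)

    def test_downsample_removes_stopband_tone(self):
        raw = tone(900.0, fs=2000.0, dur_s=10.0)
        out = preprocess.downsample(raw, 500.0)
        assert np.std(out.samples[0]) < 0.05 * np.std(raw.samples[0])

    def test_downsample_identity_at_target_rate(self):
        raw = tone(100.0, fs=500.0)
        out = preprocess.downsample(raw, 500.0)
        assert np.array_equal(out.samples, raw.samples)

    def test_downsample_rejects_noninteger_ratio(self):
        raw = tone(100.0, fs=512.0)
        with pytest.raises(ValueError):
            preprocess.downsample(raw, 500.0)


class TestExtractEnvelope:
    def test_in_band_tone_amplitude_recovered(self):
        raw = tone(90.0, amp=2.0, dur_s=10.0)
        env = preprocess.extract_envelope(raw)
        inner = env.values[0][2:-2]  # edges see filter transients
        assert inner == pytest.approx(np.full_like(inner, 2.0), rel=0.03)

    def test_modulated_carrier_tracks_modulator(self):
        fs, dur = 512.0, 60.0
        t = np.arange(int(fs * dur)) / fs
        mod = 0.5 + 0.25 * np.sin(2 * np.pi * 0.2 * t)
        raw = RawRecording((mod * np.sin(2 * np.pi * 90 * t))[None, :], fs, ["a"])
        env = preprocess.extract_envelope(raw)
        mod_b = mod[: env.n_bins * 128].reshape(-1, 128).mean(axis=1)
        assert np.corrcoef(env.values[0], mod_b)[0, 1] > 0.98

    def test_out_of_band_tone_rejected(self):
        raw = tone(30.0, dur_s=10.0)
        env = preprocess.extract_envelope(raw)
        assert np.median(env.values) < 0.02

    def test_too_short_recording_raises(self):
        raw = RawRecording(np.zeros((1, 64)), 512.0, ["a"])
        with pytest.raises(ValueError, match="shorter"):
            preprocess.extract_envelope(raw)


class TestDespike:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([1.0, 1.0, 20.0, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0, 1.0]),
            ([1.0, 1.0, 6.9, 1.0, 1.0], [1.0, 1.0, 6.9, 1.0, 1.0]),
            ([10.0, 1.0, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0]),
        ],
    )
    def test_hand_computed_toys(self, x, expected):
        env = EnvelopeSeries(np.asarray([x]))
        out = preprocess.despike_envelope(env)
        assert np.array_equal(out.values[0], expected)

    def test_interpolation_between_unequal_neighbors(self):
        env = EnvelopeSeries(np.array([[1.0, 2.0, 50.0, 4.0, 5.0]]))
        out = preprocess.despike_envelope(env)
        assert out.values[0, 2] == pytest.approx(3.0)

    def test_respects_segment_boundaries(self):
        vals = np.array([[1.0, 1.0, 20.0, 5.0, 5.0, 5.0]])
        env = EnvelopeSeries(vals, segment_bounds=[(0, 3), (3, 6)])
        out = preprocess.despike_envelope(env)
        # spike at the edge of segment 1 takes segment-internal neighbor value
        assert np.array_equal(out.values[0], [1.0, 1.0, 1.0, 5.0, 5.0, 5.0])

    def test_all_flagged_segment_is_hard_error(self):
        env = EnvelopeSeries(np.array([[-1.0, -1.0, -1.0]]))  # median < 0: all above 7*med
        with pytest.raises(RuntimeError):
            preprocess.despike_envelope(env)


class TestZscore:
    def test_windows_have_zero_mean_unit_sd(self, rng):
        env = EnvelopeSeries(rng.gamma(2.0, 2.0, (3, 3600)))
        out = preprocess.zscore_segments(env, 300.0)
        for s in range(0, 3600, 1200):
            block = out.values[:, s : s + 1200]
            assert np.abs(block.mean(axis=1)).max() < 1e-10
            assert np.abs(block.std(axis=1, ddof=1) - 1).max() < 1e-10

    def test_offset_invariance(self, rng):
        base = rng.standard_normal((2, 2400))
        env_a = EnvelopeSeries(base)
        env_b = EnvelopeSeries(base + 7.0)
        a = preprocess.zscore_segments(env_a, 300.0)
        b = preprocess.zscore_segments(env_b, 300.0)
        assert np.allclose(a.values, b.values)

    def test_linear_ramp_first_value_matches_oracle(self):
        ramp = np.arange(1200, dtype=float)
        env = EnvelopeSeries(ramp[None, :])
        out = preprocess.zscore_segments(env, 300.0)
        window = ramp[:1200]
        oracle = (0.0 - window.mean()) / window.std(ddof=1)
        assert out.values[0, 0] == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_window_flagged_to_zero(self):
        env = EnvelopeSeries(np.ones((1, 1200)))
        with pytest.warns(UserWarning, match="zero-variance"):
            out = preprocess.zscore_segments(env, 300.0)
        assert np.array_equal(out.values, np.zeros((1, 1200)))


def test_full_chain_is_deterministic(rng):
    x = rng.standard_normal((4, 512 * 40)) + 6.0
    raw = RawRecording(x, 512.0, [f"G{i}" for i in range(4)])
    a, _ = preprocess.condition_recording(raw, modality="ecog")
    b, _ = preprocess.condition_recording(raw, modality="ecog")
    assert np.array_equal(a.values, b.values)


def test_seeg_chain_downsamples_and_bipolar_references(rng):
    x = rng.standard_normal((4, 2000 * 40))
    raw = RawRecording(x, 2000.0, ["A1", "A2", "A3", "A4"], modality="seeg")
    env, mask = preprocess.condition_recording(raw, reject=False)
    assert env.n_bins == 40 * 4
    assert all("-" in c for c in env.channel_ids)
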