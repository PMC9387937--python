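"""Synthetic multichannel recordings with planted behavioral-state structure.

Every downstream stage of the pipeline is verified against recordings built
here: 5-minute blocks of labeled "behavioral states", each state defined by a
:class:`StateSpec` that plants channel means, channel variances, a loading
matrix onto latent Gaussian-process factors with per-factor timescales, and the
relative strength of each factor.  The generator can emit either the binned
envelope directly (for feature/decoder tests against exact ground truth) or a
raw microvolt-like recording (70-110 Hz amplitude-modulated carriers plus 1/f
background, line noise, and sparse amplitude spikes) whose conditioning
round-trips through :mod:`hgstates.preprocess`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import BIN_MS, EnvelopeSeries, RawRecording

#: GP noise floor: kernel = (1 - sigma_n^2) exp(-dt^2 / 2 tau^2) + sigma_n^2 I
SIGMA_N_SQ = 1e-3


# --------------------------------------------------------------------------- #
# containers
# --------------------------------------------------------------------------- #

@dataclass
class StateSpec:
    """Generative parameters of one behavioral state.

    Per 250 ms bin in this state the q-channel envelope is

        y_t = channel_mean + diag(channel_sd) (L (s * x_t) + eps_t)

    with ``L`` the loading matrix (q x p), ``s`` the per-factor scale,
    ``x_t`` unit-variance GP latents with timescales ``taus_ms``, and
    ``eps_t`` i.i.d. standard normal.  The planted covariance before the
    ``channel_sd`` scaling is therefore ``L diag(s^2) L' + I``.
    """

    name: str
    channel_mean: np.ndarray
    channel_sd: np.ndarray
    loading: np.ndarray
    taus_ms: np.ndarray
    factor_scale: np.ndarray

    def __post_init__(self) -> None:
        self.channel_mean = np.asarray(self.channel_mean, dtype=float)
        self.channel_sd = np.asarray(self.channel_sd, dtype=float)
        self.loading = np.atleast_2d(np.asarray(self.loading, dtype=float))
        self.taus_ms = np.atleast_1d(np.asarray(self.taus_ms, dtype=float))
        self.factor_scale = np.atleast_1d(np.asarray(self.factor_scale, dtype=float))
        q, p = self.loading.shape
        if self.channel_mean.shape != (q,) or self.channel_sd.shape != (q,):
            raise ValueError("channel_mean/channel_sd must have one entry per channel")
        if self.taus_ms.shape != (p,) or self.factor_scale.shape != (p,):
            raise ValueError("taus_ms/factor_scale must have one entry per factor")
        if np.any(self.channel_sd <= 0):
            raise ValueError("channel_sd must be positive")
        if np.any(self.taus_ms <= 0):
            raise ValueError("taus_ms must be positive")
        if np.any(np.all(self.loading == 0, axis=0)):
            raise ValueError("loading has an all-zero column")

    @property
    def n_channels(self) -> int:
        return self.loading.shape[0]

    @property
    def n_factors(self) -> int:
        return self.loading.shape[1]

    def planted_cov(self) -> np.ndarray:
        """Planted per-bin channel covariance of the envelope."""
        L = self.loading * self.factor_scale
        inner = L @ L.T + np.eye(self.n_channels)
        return np.outer(self.channel_sd, self.channel_sd) * inner


@dataclass
class Schedule:
    """Ordered 5-minute-style block schedule of behavioral states."""

    blocks: list[tuple[str, float]]
    block_len_s: float = 300.0

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("schedule is empty")
        if any(d <= 0 for _, d in self.blocks):
            raise ValueError("block durations must be positive")

    @classmethod
    def repeated(
        cls, states: list[str], n_repeats: int, block_len_s: float = 300.0
    ) -> "Schedule":
        """Interleave ``states`` round-robin, ``n_repeats`` blocks each."""
        blocks = [(s, block_len_s) for _ in range(n_repeats) for s in states]
        return cls(blocks, block_len_s)

    @property
    def total_s(self) -> float:
        return float(sum(d for _, d in self.blocks))

    def to_frame(self) -> pd.DataFrame:
        """Labeled blocks as a (start_s, end_s, state) table."""
        start = np.concatenate([[0.0], np.cumsum([d for _, d in self.blocks])[:-1]])
        return pd.DataFrame(
            {
                "start_s": start,
                "end_s": start + [d for _, d in self.blocks],
                "state": [s for s, _ in self.blocks],
            }
        )


@dataclass
class GroundTruth:
    """What was planted: latent paths, bin labels, and the state specs."""

    latent_paths: np.ndarray  # (p_true, T_total)
    state_of_bin: np.ndarray  # (T_total,) state names
    specs: dict[str, StateSpec]
    seed: int


# --------------------------------------------------------------------------- #
# GP latents
# --------------------------------------------------------------------------- #

def gp_kernel(tau_ms: float, T: int, bin_ms: float = BIN_MS, sigma_n_sq: float = SIGMA_N_SQ) -> np.ndarray:
    """Squared-exponential GP covariance over ``T`` bins with unit variance.

    K(t1, t2) = (1 - sigma_n_sq) exp(-(t1-t2)^2 / (2 tau^2)) + sigma_n_sq [t1=t2]
    """
    if tau_ms <= 0 or bin_ms <= 0:
        raise ValueError("tau_ms and bin_ms must be positive")
    t = np.arange(T) * bin_ms
    dt = t[:, None] - t[None, :]
    K = (1.0 - sigma_n_sq) * np.exp(-(dt**2) / (2.0 * tau_ms**2))
    K[np.diag_indices(T)] += sigma_n_sq
    return K


def sample_gp_latents(
    taus_ms,
    T: int,
    bin_ms: float = BIN_MS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    sigma_n_sq: float = SIGMA_N_SQ,
    _chol_cache: dict | None = None,
) -> np.ndarray:
    """Draw zero-mean, unit-variance GP latents, one row per timescale."""
    taus_ms = np.atleast_1d(np.asarray(taus_ms, dtype=float))
    if T < 1:
        raise ValueError("T must be >= 1")
    if np.any(taus_ms <= 0):
        raise ValueError("taus_ms must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    cache = _chol_cache if _chol_cache is not None else {}
    out = np.empty((taus_ms.size, T))
    for i, tau in enumerate(taus_ms):
        key = (float(tau), T)
        if key not in cache:
            cache[key] = np.linalg.cholesky(gp_kernel(tau, T, bin_ms, sigma_n_sq))
        out[i] = cache[key] @ rng.standard_normal(T)
    return out


def sample_gpfa_epochs(
    C: np.ndarray,
    d: np.ndarray,
    R: np.ndarray,
    taus_ms,
    n_epochs: int,
    T: int,
    bin_ms: float = BIN_MS,
    seed: int | None = None,
    sigma_n_sq: float = SIGMA_N_SQ,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw i.i.d. epochs from the GPFA observation model.

    Returns ``(epochs, latents)`` with shapes (E, q, T) and (E, p, T); ``R``
    is the diagonal of the observation noise covariance.
    """
    rng = np.random.default_rng(seed)
    C = np.asarray(C, float)
    d = np.asarray(d, float)
    R = np.asarray(R, float)
    q, p = C.shape
    cache: dict = {}
    X = np.empty((n_epochs, p, T))
    Y = np.empty((n_epochs, q, T))
    for e in range(n_epochs):
        x = sample_gp_latents(taus_ms, T, bin_ms, rng=rng, sigma_n_sq=sigma_n_sq, _chol_cache=cache)
        eps = rng.standard_normal((q, T)) * np.sqrt(R)[:, None]
        X[e] = x
        Y[e] = C @ x + d[:, None] + eps
    return Y, X


# --------------------------------------------------------------------------- #
# envelope-level generation
# --------------------------------------------------------------------------- #

def generate_envelope_dataset(
    specs: list[StateSpec],
    schedule: Schedule,
    seed: int,
    bin_ms: float = BIN_MS,
    clip_at_zero: bool = False,
    channel_ids: list[str] | None = None,
) -> tuple[EnvelopeSeries, pd.DataFrame, GroundTruth]:
    """Generate a binned envelope with planted per-state statistics.

    Latents restart at every block boundary (blocks are generated as
    independent GP draws), so within-block statistics match the state spec
    exactly.  Returns the envelope, the labeled block table
    (start_s/end_s/state), and the planted ground truth.
    """
    by_name = {s.name: s for s in specs}
    if len(by_name) != len(specs):
        raise ValueError("duplicate state names")
    q = specs[0].n_channels
    p = specs[0].n_factors
    if any(s.n_channels != q for s in specs):
        raise ValueError("all state specs must share the channel count q")
    if any(s.n_factors != p for s in specs):
        raise ValueError("all state specs must share the latent dimensionality")
    for name, _ in schedule.blocks:
        if name not in by_name:
            raise ValueError(f"schedule references unknown state {name!r}")

    rng = np.random.default_rng(seed)
    cache: dict = {}
    values, latents, labels = [], [], []
    for name, dur_s in schedule.blocks:
        spec = by_name[name]
        nb = int(round(dur_s * 1000.0 / bin_ms))
        x = sample_gp_latents(spec.taus_ms, nb, bin_ms, rng=rng, _chol_cache=cache)
        eps = rng.standard_normal((q, nb))
        y = spec.channel_mean[:, None] + spec.channel_sd[:, None] * (
            spec.loading @ (spec.factor_scale[:, None] * x) + eps
        )
        values.append(y)
        latents.append(x)
        labels.append(np.full(nb, name))

    y = np.concatenate(values, axis=1)
    if clip_at_zero:
        y = np.clip(y, 0.0, None)
    env = EnvelopeSeries(y, bin_ms=bin_ms, channel_ids=channel_ids or [])
    gt = GroundTruth(
        latent_paths=np.concatenate(latents, axis=1),
        state_of_bin=np.concatenate(labels),
        specs=by_name,
        seed=seed,
    )
    return env, schedule.to_frame(), gt


# --------------------------------------------------------------------------- #
# raw-recording synthesis
# --------------------------------------------------------------------------- #

@dataclass
class NoiseConfig:
    """Additive-noise levels for raw synthesis, relative to the median envelope.

    ``pink_rel``/``line_rel`` scale the broadband 1/f background and the 60 Hz
    fundamental (harmonics fall off as 1/k).  Spikes are short 70-110 Hz bursts
    with Poisson arrivals at ``spike_rate_hz`` and amplitude
    ``spike_amp_factor`` times the channel median envelope; the default
    duration guarantees that at least one 250 ms bin is fully covered by the
    burst, so its bin-averaged amplitude actually trips the 7x-median
    despiking rule downstream (a shorter burst straddling a bin edge would
    dilute below threshold).
    """

    pink_rel: float = 0.2
    line_rel: float = 0.5
    line_hz: float = 60.0
    n_harmonics: int = 4
    spike_rate_hz: float = 1.0 / 300.0
    spike_amp_factor: float = 10.0
    spike_dur_s: float = 0.75

    @classmethod
    def none(cls) -> "NoiseConfig":
        return cls(pink_rel=0.0, line_rel=0.0, spike_rate_hz=0.0)


def _pink_noise(n: int, rng: np.random.Generator, f_floor_hz: float, fs: float) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise (flat below ``f_floor_hz``)."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec /= np.sqrt(np.maximum(f, f_floor_hz))
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def generate_raw_recording(
    env: EnvelopeSeries,
    fs_hz: float,
    carrier_band: tuple[float, float] = (70.0, 110.0),
    noise: NoiseConfig | None = None,
    seed: int = 0,
    modality: str = "ecog",
) -> RawRecording:
    """Turn a binned envelope into a raw microvolt-like recording.

    Each channel is a band-limited unit-variance noise carrier (white noise
    band-passed to ``carrier_band``), amplitude-modulated by the linearly
    interpolated envelope, plus 1/f background noise, line noise and
    harmonics, and sparse high-amplitude bursts.  Running the conditioning
    chain on the output recovers the input envelope up to an affine scale.
    """
    noise = noise if noise is not None else NoiseConfig()
    lo, hi = carrier_band
    if fs_hz < 2.2 * hi:
        raise ValueError(f"fs {fs_hz} below Nyquist margin for carrier band {carrier_band}")
    sps = fs_hz * env.bin_ms / 1000.0
    if abs(sps - round(sps)) > 1e-9:
        raise ValueError("envelope bin width must divide evenly into samples")
    sps = int(round(sps))
    if np.any(env.values < 0):
        raise ValueError("raw synthesis requires a non-negative envelope")

    rng = np.random.default_rng(seed)
    q, T = env.values.shape
    n = T * sps
    t = np.arange(n) / fs_hz
    sos = signal.butter(4, carrier_band, btype="bandpass", fs=fs_hz, output="sos")

    # line noise is coherent across channels (one phase per harmonic), as real
    # mains pickup is; a common-average reference can then remove it
    line_phases = rng.uniform(0, 2 * np.pi, noise.n_harmonics)

    out = np.empty((q, n))
    for ch in range(q):
        # zero-order hold: each bin's amplitude is constant across its samples,
        # so the planted bin value is exactly the within-bin mean amplitude
        modulator = np.repeat(env.values[ch], sps)
        carrier = signal.sosfiltfilt(sos, rng.standard_normal(n))
        carrier /= carrier.std()
        x = modulator * carrier
        med = np.median(env.values[ch])
        if noise.pink_rel > 0:
            x = x + noise.pink_rel * med * _pink_noise(n, rng, f_floor_hz=1.0, fs=fs_hz)
        if noise.line_rel > 0:
            for k in range(1, noise.n_harmonics + 1):
                f0 = noise.line_hz * k
                if f0 >= fs_hz / 2:
                    break
                amp = noise.line_rel * med / k
                x = x + amp * np.sin(2 * np.pi * f0 * t + line_phases[k - 1])
        if noise.spike_rate_hz > 0:
            n_spikes = rng.poisson(noise.spike_rate_hz * n / fs_hz)
            width = int(round(noise.spike_dur_s * fs_hz))
            # burst onsets snap to the 250 ms bin grid so each contaminated bin
            # is fully covered: its bin-averaged amplitude then clearly exceeds
            # the 7x-median despiking threshold and the rule can repair it from
            # uncontaminated neighbors (a burst straddling a bin edge would
            # leave sub-threshold residue the rule cannot see)
            width = max(width // sps, 1) * sps
            tb = np.arange(width) / fs_hz
            # the amplitude factor applies on the raw envelope's own scale:
            # the unit-variance carrier's analytic envelope averages sqrt(pi/2)
            amp = noise.spike_amp_factor * np.sqrt(np.pi / 2) * med
            for _ in range(n_spikes):
                start = int(rng.integers(0, max((n - width) // sps, 1))) * sps
                # lightly tapered in-band chirp: deterministic envelope, so
                # every fully covered bin reliably exceeds the despiking
                # threshold, and the short flanks leave little sub-threshold
                # contamination in the partially covered neighbors
                burst = signal.windows.tukey(width, 0.15) * np.sin(
                    2 * np.pi * (lo + 5 + (hi - lo - 10) * tb / (2 * noise.spike_dur_s)) * tb
                    + rng.uniform(0, 2 * np.pi)
                )
                x[start : start + width] += amp * burst
        out[ch] = x

    return RawRecording(out, fs_hz=fs_hz, channel_ids=list(env.channel_ids), modality=modality)


# --------------------------------------------------------------------------- #
# study-condition presets
# --------------------------------------------------------------------------- #

def _patterns(q: int) -> dict[str, np.ndarray]:
    """A small bank of orthogonal unit-norm sign patterns over q channels."""
    idx = np.arange(q)
    raw = {
        "uniform": np.ones(q),
        "alternating": np.where(idx % 2 == 0, 1.0, -1.0),
        "halves": np.where(idx < q // 2, 1.0, -1.0),
        "pairs": np.where((idx // 2) % 2 == 0, 1.0, -1.0),
    }
    return {k: v / np.linalg.norm(v) for k, v in raw.items()}


def demo_state_specs(q: int = 12) -> list[StateSpec]:
    """Four behavioral states with all four planted differences.

    The states differ in channel means (level plus a channel pattern), channel
    SDs, loading sign structure (hence covariance), and in how envelope power
    splits between a slow (tau of several seconds) and a fast (sub-second tau)
    factor.  These are the default study conditions used by the feature-family
    decoding analysis.
    """
    pat = _patterns(q)
    sq = np.sqrt(q)

    def spec(name, level, mean_pat, sd, cols, taus, scales):
        mean = level + (0.8 * sq * pat[mean_pat] if mean_pat else 0.0)
        loading = 1.2 * np.column_stack([pat[c] for c in cols])
        return StateSpec(
            name=name,
            channel_mean=np.full(q, float(level)) + (mean - level),
            channel_sd=np.full(q, float(sd)),
            loading=loading,
            taus_ms=np.asarray(taus, float),
            factor_scale=np.asarray(scales, float),
        )

    return [
        spec("rest", 8.0, None, 1.0, ("uniform", "alternating"), (8000.0, 500.0), (1.6, 0.6)),
        spec("dialogue", 9.5, "alternating", 1.5, ("halves", "pairs"), (4000.0, 250.0), (0.6, 1.6)),
        spec("electronics", 7.0, "halves", 2.0, ("alternating", "halves"), (8000.0, 250.0), (1.2, 1.2)),
        spec("television", 9.0, "pairs", 0.8, ("pairs", "uniform"), (4000.0, 500.0), (1.6, 1.6)),
    ]


def covariance_only_state_specs(q: int = 8) -> list[StateSpec]:
    """Three states that differ ONLY in covariance structure.

    Channel means, channel SDs, factor timescales and factor strengths are all
    shared; only the loading sign patterns differ, so after per-window
    z-scoring the states are separable purely by inter-channel correlation
    (and by latent-factor covariance), not by any mean shift.
    """
    pat = _patterns(q)
    taus = np.array([2000.0, 500.0])
    scales = np.array([1.4, 1.4])

    def spec(name, cols):
        return StateSpec(
            name=name,
            channel_mean=np.full(q, 8.0),
            channel_sd=np.ones(q),
            loading=1.2 * np.column_stack([pat[c] for c in cols]),
            taus_ms=taus,
            factor_scale=scales,
        )

    return [
        spec("covA", ("uniform", "alternating")),
        spec("covB", ("halves", "pairs")),
        spec("covC", ("alternating", "uniform")),
    ]


def smooth_latent_state_specs(q: int = 10) -> list[StateSpec]:
    """Two states driven by genuinely smooth latents (taus of 1-8 s).

    Used for the model-comparison analysis where temporal smoothing should pay
    off: a GP factor model with the right kernel should reconstruct held-out
    channels better than time-independent factor analysis.
    """
    rng = np.random.default_rng(20240817)
    taus = np.array([1000.0, 3000.0, 8000.0])

    def spec(name):
        L = rng.standard_normal((q, taus.size))
        L /= np.linalg.norm(L, axis=0)
        return StateSpec(
            name=name,
            channel_mean=np.full(q, 8.0),
            channel_sd=np.ones(q),
            loading=1.3 * L,
            taus_ms=taus,
            factor_scale=np.array([1.2, 1.2, 1.2]),
        )

    return [spec("smoothA"), spec("smoothB")]


def roundtrip_state_specs(q: int = 10) -> list[StateSpec]:
    """Two deeply modulated, slowly varying states for raw-synthesis tests.

    The planted envelope's coefficient of variation (~0.65) is set well above
    the per-bin Rayleigh noise of the stochastic 70-110 Hz carrier (~0.16 for
    a 40 Hz bandwidth averaged over 250 ms), and most of that variance is
    carried by the smooth factors rather than by bin-to-bin noise (which
    filter smearing at bin edges degrades), so that envelope recovery through
    the conditioning chain is limited by the additive noise sources rather
    than by the carrier construct itself.
    """
    pat = _patterns(q)
    taus = np.array([8000.0, 2000.0])
    scales = np.array([3.0, 1.5])

    def spec(name, cols):
        return StateSpec(
            name=name,
            channel_mean=np.full(q, 6.0),
            channel_sd=np.full(q, 2.4),
            loading=1.2 * np.column_stack([pat[c] for c in cols]),
            taus_ms=taus,
            factor_scale=scales,
        )

    return [spec("deepA", ("uniform", "alternating")), spec("deepB", ("halves", "pairs"))]


def recovery_ground_truth(
    q: int = 12, p: int = 3, seed: int = 7, taus_ms=(300.0, 1500.0, 8000.0)
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Ground-truth GPFA parameters (C, d, R, taus) for parameter recovery.

    Loading columns are random with unit norm; observation noise is set so each
    channel carries a workable signal-to-noise ratio for EM.
    """
    taus_ms = np.asarray(taus_ms, float)
    if taus_ms.size != p:
        raise ValueError("taus_ms must have length p")
    rng = np.random.default_rng(seed)
    C = rng.standard_normal((q, p))
    C /= np.linalg.norm(C, axis=0)
    d = rng.uniform(-1, 1, q)
    R = np.full(q, 0.15)
    return C, d, R, taus_ms
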