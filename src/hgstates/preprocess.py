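"""Conditioning of raw intracranial recordings into binned high-gamma amplitude.

The chain mirrors standard intracranial practice for estimating population
firing from the field potential: reject noise-corrupted channels, re-reference
(common average for subdural grids, bipolar pairs for depth electrodes),
down-sample depth recordings, notch out line noise and harmonics, band-pass
70-110 Hz, take the magnitude of the analytic signal (Hilbert transform) as the
amplitude envelope, average it over non-overlapping 250 ms bins, and replace
outlier bins (despiking). The binned envelope is the square root of band power
and serves as the proxy for local neuronal firing rate in everything downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

#: default high-gamma band (Hz)
HIGH_GAMMA_BAND = (70.0, 110.0)
#: default envelope bin width (ms)
BIN_MS = 250.0
#: line-noise notch centers (Hz)
NOTCH_CENTERS = (60.0, 120.0, 180.0, 240.0)


# --------------------------------------------------------------------------- #
# containers
# --------------------------------------------------------------------------- #

@dataclass
class RawRecording:
    """Continuous multichannel recording (microvolt-like units).

    ``samples`` is (q, N); ``modality`` is ``"ecog"`` (subdural grid) or
    ``"seeg"`` (depth electrodes, bipolar-referenced along shanks).
    """

    samples: np.ndarray
    fs_hz: float
    channel_ids: list[str]
    modality: str = "ecog"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError("channel_ids length must match channel count")
        if self.modality not in ("ecog", "seeg"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("raw samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class EnvelopeSeries:
    """Binned high-gamma amplitude, (q, T) at one bin per ``bin_ms``.

    ``segment_bounds`` lists half-open bin ranges of contiguous recording;
    they partition [0, T).  Filtering/interpolation steps never cross a
    segment boundary.
    """

    values: np.ndarray
    bin_ms: float = BIN_MS
    segment_bounds: list[tuple[int, int]] = field(default_factory=list)
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (channels x bins)")
        if not self.segment_bounds:
            self.segment_bounds = [(0, self.values.shape[1])]
        if not self.channel_ids:
            self.channel_ids = [f"ch{i}" for i in range(self.values.shape[0])]
        if len(self.channel_ids) != self.values.shape[0]:
            raise ValueError("channel_ids length must match channel count")
        bounds = sorted(self.segment_bounds)
        if bounds[0][0] != 0 or bounds[-1][1] != self.values.shape[1]:
            raise ValueError("segment_bounds must cover [0, T)")
        for (a0, a1), (b0, _) in zip(bounds, bounds[1:]):
            if a1 != b0:
                raise ValueError("segment_bounds must partition [0, T)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("envelope contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def fs_hz(self) -> float:
        """Sampling rate of the binned series (4 Hz at 250 ms bins)."""
        return 1000.0 / self.bin_ms

    def bin_times_s(self) -> np.ndarray:
        """Center time of every bin, seconds."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_ms / 1000.0


@dataclass
class ChannelMask:
    """Per-channel keep/reject decision with a reason tag for rejections."""

    channel_ids: list[str]
    keep: np.ndarray
    reason: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if len(self.channel_ids) != self.keep.size:
            raise ValueError("keep must align with channel_ids")

    @property
    def kept_ids(self) -> list[str]:
        return [c for c, k in zip(self.channel_ids, self.keep) if k]


# --------------------------------------------------------------------------- #
# channel rejection and referencing
# --------------------------------------------------------------------------- #

#: rejection threshold in SD units per modality
REJECT_SD = {"ecog": 3.0, "seeg": 1.5}


def reject_channels(raw: RawRecording, modality: str | None = None) -> ChannelMask:
    """Reject noise-corrupted channels by mean squared signal value.

    A channel is rejected when its mean squared value exceeds the across-channel
    mean by more than k standard deviations (k = 3 for ECoG, 1.5 for sEEG), or
    when it contains samples exactly equal to zero (dead/clipped amplifier
    output).
    """
    modality = modality or raw.modality
    if modality not in REJECT_SD:
        raise ValueError(f"unknown modality {modality!r}")
    if raw.n_channels < 3:
        raise ValueError("need at least 3 channels to estimate a rejection threshold")

    power = np.mean(raw.samples**2, axis=1)
    thresh = power.mean() + REJECT_SD[modality] * power.std(ddof=0)
    keep = power <= thresh
    reason = {c: "power" for c, k in zip(raw.channel_ids, keep) if not k}

    has_zero = np.any(raw.samples == 0.0, axis=1)
    for i, z in enumerate(has_zero):
        if z and keep[i]:
            keep[i] = False
            reason[raw.channel_ids[i]] = "zeros"

    if not keep.any():
        raise RuntimeError("all channels rejected")
    for cid in reason:
        logger.info("rejected channel %s (%s)", cid, reason[cid])
    return ChannelMask(list(raw.channel_ids), keep, reason)


def apply_mask(raw: RawRecording, mask: ChannelMask) -> RawRecording:
    """Drop rejected channels from a recording."""
    idx = np.flatnonzero(mask.keep)
    return replace(
        raw,
        samples=raw.samples[idx],
        channel_ids=[raw.channel_ids[i] for i in idx],
    )


def _shank_of(channel_id: str) -> str:
    """Leading non-digit prefix of a contact label ("A12" -> "A")."""
    prefix = channel_id.rstrip("0123456789")
    if not prefix or prefix == channel_id:
        raise ValueError(
            f"channel id {channel_id!r} has no shank prefix + contact number"
        )
    return prefix


def rereference(raw: RawRecording, scheme: str = "common_average") -> RawRecording:
    """Re-reference a recording.

    ``common_average`` subtracts the instantaneous mean of all (kept) channels;
    ``bipolar_pairs`` differences adjacent contacts along each shank, inferring
    shank membership from the channel-id prefix ("A1", "A2", ... -> "A1-A2").
    """
    if scheme == "none":
        return raw
    if scheme == "common_average":
        return replace(raw, samples=raw.samples - raw.samples.mean(axis=0, keepdims=True))
    if scheme == "bipolar_pairs":
        shanks: dict[str, list[int]] = {}
        for i, cid in enumerate(raw.channel_ids):
            shanks.setdefault(_shank_of(cid), []).append(i)
        out, ids = [], []
        for contacts in shanks.values():
            for a, b in zip(contacts, contacts[1:]):
                out.append(raw.samples[a] - raw.samples[b])
                ids.append(f"{raw.channel_ids[a]}-{raw.channel_ids[b]}")
        if not out:
            raise ValueError("bipolar referencing produced no channel pairs")
        return replace(raw, samples=np.asarray(out), channel_ids=ids)
    raise ValueError(f"unknown reference scheme {scheme!r}")


# --------------------------------------------------------------------------- #
# filtering
# --------------------------------------------------------------------------- #

def notch_filter(
    raw: RawRecording, centers: tuple[float, ...] = NOTCH_CENTERS, bandwidth_hz: float = 1.0
) -> RawRecording:
    """Zero-phase IIR notch at each line-noise harmonic below Nyquist.

    Each notch is a 2nd-order IIR with -3 dB bandwidth ``bandwidth_hz``,
    applied forward-backward (so the effective attenuation at the center
    doubles in dB and the phase response is flat).
    """
    x = raw.samples
    for f0 in centers:
        if f0 >= raw.fs_hz / 2:
            logger.warning("notch center %.0f Hz >= Nyquist; skipped", f0)
            continue
        b, a = signal.iirnotch(f0, Q=f0 / bandwidth_hz, fs=raw.fs_hz)
        x = signal.filtfilt(b, a, x, axis=1)
    return replace(raw, samples=x)


def downsample(raw: RawRecording, target_fs: float = 500.0) -> RawRecording:
    """Integer-ratio decimation with an anti-aliasing low-pass.

    An 8th-order zero-phase Butterworth low-pass at 0.8x the target Nyquist is
    applied before keeping every ``fs/target_fs``-th sample.
    """
    ratio = raw.fs_hz / target_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"fs {raw.fs_hz} not an integer multiple of target {target_fs}")
    ratio = int(round(ratio))
    if ratio == 1:
        return raw
    sos = signal.butter(8, 0.8 * (target_fs / 2), btype="low", fs=raw.fs_hz, output="sos")
    x = signal.sosfiltfilt(sos, raw.samples, axis=1)
    return replace(raw, samples=x[:, ::ratio], fs_hz=target_fs)


def extract_envelope(
    raw: RawRecording,
    band: tuple[float, float] = HIGH_GAMMA_BAND,
    bin_ms: float = BIN_MS,
) -> EnvelopeSeries:
    """Band-pass, Hilbert-transform, and bin the amplitude envelope.

    Per channel: 4th-order zero-phase Butterworth band-pass to ``band``, then
    the magnitude of the analytic signal, then the mean over consecutive
    non-overlapping ``bin_ms`` bins (the square root of band power per bin).
    A trailing partial bin is dropped.
    """
    lo, hi = band
    if not 0 < lo < hi < raw.fs_hz / 2:
        raise ValueError(f"band {band} outside (0, fs/2) for fs={raw.fs_hz}")
    sps = raw.fs_hz * bin_ms / 1000.0
    if abs(sps - round(sps)) > 1e-9:
        raise ValueError("bin_ms must correspond to an integer number of samples")
    sps = int(round(sps))
    if raw.n_samples < sps:
        raise ValueError("recording shorter than one bin")

    sos = signal.butter(4, band, btype="bandpass", fs=raw.fs_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, raw.samples, axis=1)
    amp = np.abs(signal.hilbert(filtered, axis=1))
    n_bins = raw.n_samples // sps
    binned = amp[:, : n_bins * sps].reshape(raw.n_channels, n_bins, sps).mean(axis=2)
    return EnvelopeSeries(
        binned, bin_ms=bin_ms, segment_bounds=[(0, n_bins)], channel_ids=list(raw.channel_ids)
    )


# --------------------------------------------------------------------------- #
# envelope-domain cleanup
# --------------------------------------------------------------------------- #

def _despike_1d(x: np.ndarray, k: float) -> np.ndarray:
    med = np.median(x)
    bad = x > k * med
    if bad.all():
        raise RuntimeError("all bins flagged as spikes in a segment")
    if not bad.any():
        return x
    out = x.copy()
    good = np.flatnonzero(~bad)
    # np.interp clamps to the nearest good value beyond the edges
    out[bad] = np.interp(np.flatnonzero(bad), good, x[good])
    return out


def despike_envelope(env: EnvelopeSeries, k: float = 7.0) -> EnvelopeSeries:
    """Replace envelope bins exceeding ``k`` times the channel median.

    Operates per channel and per contiguous segment; flagged bins are replaced
    by linear interpolation between the nearest unflagged neighbors (nearest
    value at segment edges).
    """
    out = env.values.copy()
    for a, b in env.segment_bounds:
        for ch in range(env.n_channels):
            out[ch, a:b] = _despike_1d(env.values[ch, a:b], k)
    return replace(env, values=out)


def zscore_segments(env: EnvelopeSeries, window_s: float = 300.0) -> EnvelopeSeries:
    """Z-score each channel within consecutive ``window_s`` windows.

    Windows tile each contiguous segment from its start (matching the 5-minute
    labeled blocks); sample SD (ddof=1).  A zero-variance window is set to 0
    with a warning rather than propagating infs.
    """
    win = window_s * 1000.0 / env.bin_ms
    if abs(win - round(win)) > 1e-9:
        raise ValueError("window_s must be an integer number of bins")
    win = int(round(win))
    out = env.values.copy()
    for a, b in env.segment_bounds:
        for s in range(a, b, win):
            e = min(s + win, b)
            block = out[:, s:e]
            mu = block.mean(axis=1, keepdims=True)
            sd = block.std(axis=1, ddof=1, keepdims=True)
            zero = (sd <= 0) | ~np.isfinite(sd)
            if zero.any():
                warnings.warn("zero-variance z-scoring window; channel set to 0")
                sd[zero] = 1.0
            block = (block - mu) / sd
            block[np.broadcast_to(zero, block.shape)] = 0.0
            out[:, s:e] = block
    return replace(env, values=out)


# --------------------------------------------------------------------------- #
# full chain
# --------------------------------------------------------------------------- #

def condition_recording(
    raw: RawRecording,
    *,
    modality: str | None = None,
    reference: str | None = None,
    reject: bool = True,
    reject_on_referenced: bool | None = None,
    notch_centers: tuple[float, ...] = NOTCH_CENTERS,
    band: tuple[float, float] = HIGH_GAMMA_BAND,
    bin_ms: float = BIN_MS,
    seeg_target_fs: float = 500.0,
    despike_k: float = 7.0,
) -> tuple[EnvelopeSeries, ChannelMask]:
    """Run the full conditioning chain on a raw recording.

    Order: referencing/rejection -> (down-sampling, sEEG only) -> notch ->
    band-pass + Hilbert + 250 ms binning -> despiking.  ``reference`` defaults
    to common average for ECoG and bipolar pairs for sEEG.  Whether rejection
    thresholds raw or referenced channels defaults to the modality convention
    (ECoG: raw channels are screened before entering the common average; sEEG:
    the bipolar pairs themselves are screened); ``reject_on_referenced``
    overrides it.
    """
    modality = modality or raw.modality
    if reference is None:
        reference = "common_average" if modality == "ecog" else "bipolar_pairs"
    if reject_on_referenced is None:
        reject_on_referenced = modality == "seeg"

    if reject and not reject_on_referenced:
        mask = reject_channels(raw, modality)
        raw = apply_mask(raw, mask)
        raw = rereference(raw, reference)
    else:
        raw = rereference(raw, reference)
        if reject:
            mask = reject_channels(raw, modality)
            raw = apply_mask(raw, mask)
        else:
            mask = ChannelMask(list(raw.channel_ids), np.ones(raw.n_channels, bool))

    if modality == "seeg" and raw.fs_hz > seeg_target_fs:
        raw = downsample(raw, seeg_target_fs)
    raw = notch_filter(raw, notch_centers)
    env = extract_envelope(raw, band=band, bin_ms=bin_ms)
    env = despike_envelope(env, k=despike_k)
    return env, mask
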