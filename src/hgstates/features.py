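"""Epoch features of the binned high-gamma envelope.

The decoding unit is a 30-second epoch (q channels x 120 bins of 250 ms).
Five feature families are derived from one envelope series:

* per-channel epoch **mean** and **variance** (computed on the raw envelope),
* the epoch **covariance** matrix (computed on the per-5-minute z-scored
  envelope, so single-channel variances carry no information),
* **slow** and **fast** band-limited amplitude: the z-scored envelope is
  low-/high-pass filtered at 0.333 Hz (3-second period), the magnitude of the
  analytic signal is taken, and averaged within each epoch.

Welch power spectral densities of the envelope (Hann window, 30-s segments
with 75% overlap, 256-point FFT) summarize per-state temporal dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import EnvelopeSeries

logger = logging.getLogger(__name__)

EPOCH_S = 30.0
BANDSPLIT_FC_HZ = 1.0 / 3.0


@dataclass
class EpochSet:
    """Labeled 30-s epochs: ``epochs`` is (E, q, T) with T bins per epoch."""

    epochs: np.ndarray
    labels: np.ndarray
    epoch_start_bin: np.ndarray
    bin_ms: float
    channel_ids: list[str] = field(default_factory=list)
    subject_tag: str = ""

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels)
        self.epoch_start_bin = np.asarray(self.epoch_start_bin, dtype=int)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (E, q, T)")
        if self.labels.shape != (self.epochs.shape[0],):
            raise ValueError("labels must align with epochs")
        if self.epoch_start_bin.shape != (self.epochs.shape[0],):
            raise ValueError("epoch_start_bin must align with epochs")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_bins(self) -> int:
        return self.epochs.shape[2]

    def start_times_s(self) -> np.ndarray:
        return self.epoch_start_bin * self.bin_ms / 1000.0

    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass
class CovFeature:
    """Per-epoch channel covariance matrices, (E, q, q), with labels."""

    matrices: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must be (E, q, q)")


# --------------------------------------------------------------------------- #
# epoching
# --------------------------------------------------------------------------- #

def epoch(
    env: EnvelopeSeries, blocks: pd.DataFrame, epoch_s: float = EPOCH_S
) -> EpochSet:
    """Tile non-overlapping ``epoch_s`` epochs within each labeled block.

    ``blocks`` has columns start_s/end_s/state.  Epochs are anchored at each
    block start, must lie entirely within one contiguous recording segment and
    one block, and are returned in chronological order.  A trailing partial
    epoch within a block is dropped.
    """
    bins_per = epoch_s * 1000.0 / env.bin_ms
    if abs(bins_per - round(bins_per)) > 1e-9:
        raise ValueError("epoch_s must be an integer number of bins")
    bins_per = int(round(bins_per))
    fs = env.fs_hz

    epochs, labels, starts = [], [], []
    for _, row in blocks.sort_values("start_s").iterrows():
        b0 = int(np.ceil(row.start_s * fs - 1e-9))
        b1 = int(np.floor(row.end_s * fs + 1e-9))
        for s in range(b0, b1 - bins_per + 1, bins_per):
            e = s + bins_per
            # keep only epochs fully inside one contiguous segment
            if any(a <= s and e <= b for a, b in env.segment_bounds):
                epochs.append(env.values[:, s:e])
                labels.append(row.state)
                starts.append(s)
    if not epochs:
        raise ValueError("no epochs could be formed from the given blocks")
    return EpochSet(
        np.asarray(epochs),
        np.asarray(labels),
        np.asarray(starts),
        bin_ms=env.bin_ms,
        channel_ids=list(env.channel_ids),
    )


# --------------------------------------------------------------------------- #
# feature families
# --------------------------------------------------------------------------- #

def epoch_mean_var(es: EpochSet) -> np.ndarray:
    """Per-epoch channel means and sample variances, concatenated (E, 2q)."""
    means = es.epochs.mean(axis=2)
    variances = es.epochs.var(axis=2, ddof=1)
    return np.concatenate([means, variances], axis=1)


def epoch_covariance(es: EpochSet) -> CovFeature:
    """Per-epoch q x q sample covariance over the epoch's bins.

    Expects epochs cut from the per-5-minute z-scored envelope, so diagonals
    are ~1 and classification cannot lean on single-channel variance.
    """
    E, q, T = es.epochs.shape
    if q > T:
        logger.warning("covariance rank-deficient: %d channels > %d bins", q, T)
    centered = es.epochs - es.epochs.mean(axis=2, keepdims=True)
    covs = np.einsum("eqt,ert->eqr", centered, centered) / (T - 1)
    covs = 0.5 * (covs + covs.transpose(0, 2, 1))
    return CovFeature(covs, es.labels.copy())


def bandsplit_features(
    env: EnvelopeSeries,
    es: EpochSet,
    fc_hz: float = BANDSPLIT_FC_HZ,
    order: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Slow/fast band-limited amplitude features, each (E, q).

    The (z-scored) envelope series is low- and high-pass filtered at ``fc_hz``
    (zero-phase Butterworth) per contiguous segment, the magnitude of each
    filtered signal's analytic signal is taken, and averaged within the epochs
    of ``es``.  Epochs falling in segments too short for stable zero-phase
    filtering are dropped by the caller's epoching, not here.
    """
    fs = env.fs_hz
    sos_lo = signal.butter(order, fc_hz, btype="low", fs=fs, output="sos")
    sos_hi = signal.butter(order, fc_hz, btype="high", fs=fs, output="sos")

    slow_env = np.empty_like(env.values)
    fast_env = np.empty_like(env.values)
    for a, b in env.segment_bounds:
        seg = env.values[:, a:b]
        lo = signal.sosfiltfilt(sos_lo, seg, axis=1)
        hi = signal.sosfiltfilt(sos_hi, seg, axis=1)
        slow_env[:, a:b] = np.abs(signal.hilbert(lo, axis=1))
        fast_env[:, a:b] = np.abs(signal.hilbert(hi, axis=1))

    T = es.n_bins
    slow = np.stack([slow_env[:, s : s + T].mean(axis=1) for s in es.epoch_start_bin])
    fast = np.stack([fast_env[:, s : s + T].mean(axis=1) for s in es.epoch_start_bin])
    return slow, fast


# --------------------------------------------------------------------------- #
# Welch PSD of the envelope
# --------------------------------------------------------------------------- #

def _sliding_periodograms(
    x: np.ndarray, fs: float, nperseg: int, noverlap: int, nfft: int
) -> np.ndarray:
    """Hann-windowed one-sided periodograms of sliding segments, (n_seg, nfft//2+1).

    Each segment is mean-detrended, Hann-windowed, zero-padded to ``nfft``;
    density scaling matches ``scipy.signal.welch``.
    """
    win = signal.windows.hann(nperseg, sym=False)
    scale = 1.0 / (fs * (win**2).sum())
    step = nperseg - noverlap
    out = []
    for s in range(0, x.size - nperseg + 1, step):
        seg = x[s : s + nperseg]
        seg = (seg - seg.mean()) * win
        spec = np.fft.rfft(seg, n=nfft)
        p = scale * np.abs(spec) ** 2
        p[1:-1] *= 2.0  # one-sided (nfft even: last bin is Nyquist)
        out.append(p)
    return np.asarray(out)


def welch_psd(
    env: EnvelopeSeries,
    blocks: pd.DataFrame,
    nperseg: int = 120,
    overlap: float = 0.75,
    nfft: int = 256,
) -> pd.DataFrame:
    """Per-state, per-channel Welch PSD of the binned envelope.

    30-second (``nperseg``-bin) Hann windows slide with ``overlap`` across
    each labeled block (restarting at block and segment boundaries), are
    zero-padded to ``nfft``, and the periodograms are averaged within state.
    The standard error is computed across the individual periodograms before
    averaging; states contributing fewer than two periodograms get NaN SE.

    Returns a long-format table (state, channel, freq_hz, power, se, n_seg).
    """
    fs = env.fs_hz
    noverlap = int(round(overlap * nperseg))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)

    # per (state, channel): list of periodograms across all usable stretches
    chunks: dict[str, list[tuple[int, int]]] = {}
    for _, row in blocks.iterrows():
        b0 = int(np.ceil(row.start_s * fs - 1e-9))
        b1 = int(np.floor(row.end_s * fs + 1e-9))
        for a, b in env.segment_bounds:
            lo, hi = max(b0, a), min(b1, b)
            if hi - lo >= nperseg:
                chunks.setdefault(row.state, []).append((lo, hi))

    records = []
    for state, spans in sorted(chunks.items()):
        for ch in range(env.n_channels):
            pgrams = [
                _sliding_periodograms(env.values[ch, a:b], fs, nperseg, noverlap, nfft)
                for a, b in spans
            ]
            P = np.concatenate(pgrams, axis=0)
            mean = P.mean(axis=0)
            se = P.std(axis=0, ddof=1) / np.sqrt(P.shape[0]) if P.shape[0] > 1 else np.full_like(mean, np.nan)
            records.append(
                pd.DataFrame(
                    {
                        "state": state,
                        "channel": env.channel_ids[ch],
                        "freq_hz": freqs,
                        "power": mean,
                        "se": se,
                        "n_seg": P.shape[0],
                    }
                )
            )
    if not records:
        raise ValueError("no block long enough for a single PSD window")
    return pd.concat(records, ignore_index=True)
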