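"""File I/O: EDF raw recordings, HDF5 envelopes/parameters, TSV tables.

EDF reading goes through ``mne.io.read_raw_edf``.  Writing uses a minimal
built-in EDF writer (16-bit samples, 1-second data records), sufficient for
round-tripping synthetic recordings through standard EDF tooling.
"""

from __future__ import annotations

import struct
from datetime import datetime
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .gpfa import GPFAParams
from .preprocess import ChannelMask, EnvelopeSeries, RawRecording
from .synthetic import GroundTruth

# --------------------------------------------------------------------------- #
# EDF
# --------------------------------------------------------------------------- #

_DIG_MIN, _DIG_MAX = -32768, 32767


def write_edf(raw: RawRecording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF with 1-second data records.

    The sampling rate must be an integer (samples per 1-s record); a trailing
    partial second is dropped.  Physical min/max per channel are taken from
    the data, so amplitude resolution is (max-min)/65535.
    """
    fs = raw.fs_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    n_rec = raw.n_samples // spr
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record")
    q = raw.n_channels
    x = raw.samples[:, : n_rec * spr]

    pmin = x.min(axis=1)
    pmax = x.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax = np.where(flat, pmin + 1.0, pmax)
    gain = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    digital = np.clip(
        np.rint((x - pmin[:, None]) * gain[:, None] + _DIG_MIN), _DIG_MIN, _DIG_MAX
    ).astype("<i2")

    def f(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    now = datetime(2000, 1, 1)
    header = b"".join(
        [
            f("0", 8),
            f("X X X X", 80),
            f("Startdate X X X X", 80),
            f(now.strftime("%d.%m.%y"), 8),
            f(now.strftime("%H.%M.%S"), 8),
            f(str(256 * (q + 1)), 8),
            f("", 44),
            f(str(n_rec), 8),
            f("1", 8),
            f(str(q), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(f(c, 16) for c in raw.channel_ids),
            b"".join(f("", 80) for _ in range(q)),  # transducer
            b"".join(f("uV", 8) for _ in range(q)),
            b"".join(f(f"{v:.6g}", 8) for v in pmin),
            b"".join(f(f"{v:.6g}", 8) for v in pmax),
            b"".join(f(str(_DIG_MIN), 8) for _ in range(q)),
            b"".join(f(str(_DIG_MAX), 8) for _ in range(q)),
            b"".join(f("", 80) for _ in range(q)),  # prefiltering
            b"".join(f(str(spr), 8) for _ in range(q)),
            b"".join(f("", 32) for _ in range(q)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(path: str | Path, modality: str = "ecog") -> RawRecording:
    """Read an EDF file into a RawRecording (microvolt units) via mne."""
    import mne

    mne_raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = mne_raw.get_data() * 1e6  # mne loads EDF uV channels as volts
    return RawRecording(
        data, fs_hz=float(mne_raw.info["sfreq"]), channel_ids=list(mne_raw.ch_names),
        modality=modality,
    )


# --------------------------------------------------------------------------- #
# HDF5 containers
# --------------------------------------------------------------------------- #

def save_envelope_dataset(
    path: str | Path,
    env: EnvelopeSeries,
    labels: pd.DataFrame | None = None,
    ground_truth: GroundTruth | None = None,
) -> None:
    """Save an envelope (and optional labels / planted ground truth) to HDF5.

    Datasets: ``envelope/values`` (q x T), ``envelope/bin_ms``,
    ``envelope/segment_bounds`` (n x 2), ``envelope/channel_ids``;
    ``labels/{start_s,end_s,state}``; ``ground_truth/{latent_paths,
    state_of_bin,seed}``.
    """
    with h5py.File(path, "w") as h:
        g = h.create_group("envelope")
        g.create_dataset("values", data=env.values)
        g.attrs["bin_ms"] = env.bin_ms
        g.create_dataset("segment_bounds", data=np.asarray(env.segment_bounds))
        g.create_dataset("channel_ids", data=[c.encode() for c in env.channel_ids])
        if labels is not None:
            gl = h.create_group("labels")
            gl.create_dataset("start_s", data=labels["start_s"].to_numpy(float))
            gl.create_dataset("end_s", data=labels["end_s"].to_numpy(float))
            gl.create_dataset("state", data=[s.encode() for s in labels["state"]])
        if ground_truth is not None:
            gt = h.create_group("ground_truth")
            gt.create_dataset("latent_paths", data=ground_truth.latent_paths)
            gt.create_dataset("state_of_bin", data=[s.encode() for s in ground_truth.state_of_bin])
            gt.attrs["seed"] = ground_truth.seed


def load_envelope_dataset(path: str | Path) -> tuple[EnvelopeSeries, pd.DataFrame | None]:
    """Load an envelope (and labels, when present) written by this package."""
    with h5py.File(path, "r") as h:
        g = h["envelope"]
        env = EnvelopeSeries(
            g["values"][()],
            bin_ms=float(g.attrs["bin_ms"]),
            segment_bounds=[tuple(b) for b in g["segment_bounds"][()]],
            channel_ids=[c.decode() for c in g["channel_ids"][()]],
        )
        labels = None
        if "labels" in h:
            gl = h["labels"]
            labels = pd.DataFrame(
                {
                    "start_s": gl["start_s"][()],
                    "end_s": gl["end_s"][()],
                    "state": [s.decode() for s in gl["state"][()]],
                }
            )
    return env, labels


def save_gpfa_params(path: str | Path, params: GPFAParams) -> None:
    """Serialize fitted GPFA/FA parameters to HDF5 (C, d, R, taus_ms, ...)."""
    with h5py.File(path, "w") as h:
        h.create_dataset("C", data=params.C)
        h.create_dataset("d", data=params.d)
        h.create_dataset("R", data=params.R)
        if params.taus_ms is not None:
            h.create_dataset("taus_ms", data=params.taus_ms)
        h.create_dataset("fit_log", data=params.fit_log)
        h.attrs["sigma_n_sq"] = params.sigma_n_sq
        h.attrs["bin_ms"] = params.bin_ms
        h.attrs["converged"] = params.converged


def load_gpfa_params(path: str | Path) -> GPFAParams:
    with h5py.File(path, "r") as h:
        return GPFAParams(
            C=h["C"][()],
            d=h["d"][()],
            R=h["R"][()],
            taus_ms=h["taus_ms"][()] if "taus_ms" in h else None,
            sigma_n_sq=float(h.attrs["sigma_n_sq"]),
            bin_ms=float(h.attrs["bin_ms"]),
            fit_log=h["fit_log"][()],
            converged=bool(h.attrs["converged"]),
        )


# --------------------------------------------------------------------------- #
# TSV tables
# --------------------------------------------------------------------------- #

def write_labels_tsv(labels: pd.DataFrame, path: str | Path) -> None:
    """Write labeled blocks as TSV (start_s, end_s, state)."""
    labels[["start_s", "end_s", "state"]].to_csv(path, sep="\t", index=False)


def write_channel_mask_tsv(mask: ChannelMask, path: str | Path) -> None:
    """Write channel keep/reject decisions as TSV (channel_id, keep, reason)."""
    pd.DataFrame(
        {
            "channel_id": mask.channel_ids,
            "keep": mask.keep.astype(int),
            "reason": [mask.reason.get(c, "") for c in mask.channel_ids],
        }
    ).to_csv(path, sep="\t", index=False)
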