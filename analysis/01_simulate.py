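#!/usr/bin/env python
"""Generate the default synthetic study dataset and write it to disk.

Four behavioral states ("rest", "dialogue", "electronics", "television") with
all four planted differences — channel means, channel variances, covariance
structure, and slow/fast latent timescales — in interleaved 5-minute blocks.
Writes the binned envelope plus labels and ground truth to HDF5, the block
labels to TSV, and a short raw ECoG-like excerpt to EDF.
"""

import argparse
from pathlib import Path

from hgstates import io, pipeline, synthetic


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    env, blocks, gt = pipeline.synthesize_default_dataset(seed=args.seed)
    io.save_envelope_dataset(args.out / "synthetic_envelope.h5", env, blocks, gt)
    io.write_labels_tsv(blocks, args.out / "labels.tsv")
    print(f"envelope: {env.n_channels} channels x {env.n_bins} bins "
          f"({env.n_bins / env.fs_hz / 60:.0f} min), {len(blocks)} labeled blocks")

    # short raw excerpt (2 blocks) so the EDF path is exercised end to end
    specs = synthetic.roundtrip_state_specs(q=8)
    sched = synthetic.Schedule([(specs[0].name, 300.0), (specs[1].name, 300.0)])
    env_rt, _, _ = synthetic.generate_envelope_dataset(
        specs, sched, seed=args.seed, clip_at_zero=True,
        channel_ids=[f"G{i + 1}" for i in range(8)],
    )
    raw = synthetic.generate_raw_recording(env_rt, fs_hz=512.0, seed=args.seed + 1)
    io.write_edf(raw, args.out / "synthetic_raw_excerpt.edf")
    print(f"raw excerpt: {raw.n_channels} channels x {raw.duration_s:.0f} s at "
          f"{raw.fs_hz:.0f} Hz -> synthetic_raw_excerpt.edf")


if __name__ == "__main__":
    main()
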