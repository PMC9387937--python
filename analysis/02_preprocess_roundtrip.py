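#!/usr/bin/env python
"""Validate the conditioning chain by round-tripping synthetic raw recordings.

Synthesizes deeply modulated raw recordings (70-110 Hz amplitude-modulated
carriers plus 1/f background, coherent line noise, and bin-aligned amplitude
spikes), conditions them (notch, band-pass, Hilbert envelope, 250 ms binning,
despiking), and correlates the recovered envelope with the planted one per
channel.  Also measures the steady-state 60 Hz notch attenuation.
"""

import argparse
import json
from pathlib import Path

from hgstates import experiments


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    out = experiments.preprocessing_roundtrip(seed=args.seed)
    (args.out / "preprocess_roundtrip.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"envelope recovery over {out['n_channels']} channels, "
          f"{out['n_bins_compared']} bins:")
    print(f"  min  channel correlation: {out['roundtrip_min_channel_corr']:.3f}")
    print(f"  med  channel correlation: {out['roundtrip_median_channel_corr']:.3f}")
    print(f"  60 Hz notch attenuation:  {out['notch_60hz_attenuation_db']:.0f} dB")
    print(f"  despiking toy cases exact: {out['despike_toys_exact']}")


if __name__ == "__main__":
    main()
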