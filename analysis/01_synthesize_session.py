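#!/usr/bin/env python
"""Generate a synthetic sine-tracking session and write its container.

The default configuration mirrors the recording protocol the pipeline
targets: 6 differential iEMG channels at 10 kHz, 9 force gauges, 6 movements
(flexion/extension pairs on three joints), 10 sine-tracking repetitions at
0.1 Hz and 20 % MVC, one leading rest second per movement, recruitment
/rate-coded motor-unit pools with powerline interference.
"""

import argparse
from pathlib import Path

import numpy as np

from iemgprop import session_io, synth


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--repetitions", type=int, default=10)
    ap.add_argument("--out", type=Path, default=None,
                    help="container directory (default results/session_<seed>)")
    args = ap.parse_args()
    out = args.out or Path("results") / f"session_{args.seed}"

    protocol = synth.ProtocolSpec(repetitions=args.repetitions)
    session = synth.assemble_session(protocol, seed=args.seed)
    session_io.write_session(session, out)
    session_io.export_label_table(session, out / "labels.csv")

    minutes = session.iemg.shape[1] / protocol.sampling_rate / 60
    print(f"session {args.seed}: {session.n_channels} iEMG channels, "
          f"{session.n_gauges} gauges, {minutes:.1f} min at {protocol.sampling_rate:.0f} Hz")
    for c, trains in session.ground_truth["spike_trains"].items():
        n_spikes = sum(t.size for t in trains)
        rms = float(np.sqrt(np.mean(session.iemg[c].astype(float) ** 2)))
        print(f"  channel {c}: {len(trains)} motor units, {n_spikes} spikes, "
              f"signal RMS {rms:.1f} uV")
    print(f"container written to {out}")


if __name__ == "__main__":
    main()
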