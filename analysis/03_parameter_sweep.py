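#!/usr/bin/env python
"""Brute-force window/threshold sweep of all fourteen feature algorithms.

For every paired segment of the session, every algorithm is evaluated on its
full parameter grid (windows 50-1050 ms step 100, shortened to 550 ms for
the dead-zone counts; Q = 0..4 step 0.2; FR quantiles 85..99); each cell
runs feature extraction, two-period calibration, force estimation and the
RMSE / Pearson metrics.  Writes one tidy CSV row per cell.
"""

import argparse
from pathlib import Path

from iemgprop import evaluate, preprocess, session_io


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--session", type=Path, default=None)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--increment-ms", type=float, default=20.0)
    ap.add_argument("--out", type=Path, default=None)
    args = ap.parse_args()
    sess_path = args.session or Path("results") / f"session_{args.seed}"
    out = args.out or Path("results") / f"sweep_{args.seed}.csv"

    session = session_io.load_session(sess_path)
    filtered = preprocess.filter_session(session)
    pairing = preprocess.pair_channels(session, iemg=filtered)
    segments = preprocess.attach_forces(
        preprocess.segment_by_cues(session, iemg=filtered), session, pairing
    )
    print(f"{len(segments)} paired segments; sweeping the full grid "
          f"at {args.increment_ms:g} ms increment ...")
    results = evaluate.run_sweep(segments, increment_ms=args.increment_ms)
    out.parent.mkdir(parents=True, exist_ok=True)
    results.to_csv(out, index=False)
    n_failed = int(results.rmse_percent.isna().sum())
    print(f"{len(results)} grid cells evaluated ({n_failed} failed cells logged); "
          f"results written to {out}")


if __name__ == "__main__":
    main()
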