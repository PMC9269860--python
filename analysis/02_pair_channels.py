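#!/usr/bin/env python
"""Comb-filter a session and pair each iEMG channel with its force gauge,
phase and movement by minimal RMSE of the normalized MAV fit.

Writes the pairing lookup table and, for synthetic sessions, scores it
against the generator's ground truth.
"""

import argparse
from pathlib import Path

from iemgprop import preprocess, session_io


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--session", type=Path, default=None,
                    help="session container (default results/session_<seed>)")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=None)
    ap.add_argument("--zero-phase", action="store_true",
                    help="use zero-phase instead of causal comb filtering")
    args = ap.parse_args()
    sess_path = args.session or Path("results") / f"session_{args.seed}"
    out = args.out or sess_path / "pairing.csv"

    session = session_io.load_session(sess_path)
    spec = preprocess.CombFilterSpec(mode="zero-phase" if args.zero_phase else "causal")
    filtered = preprocess.filter_session(session, spec)
    table = preprocess.pair_channels(session, iemg=filtered)
    table.to_csv(out)
    print(table.frame.to_string(index=False))

    if session.ground_truth and session.ground_truth.get("pairing"):
        truth = {
            r["iemg_channel"]: (r["force_gauge"], r["phase"], r["movement"])
            for r in session.ground_truth["pairing"]
        }
        hits = sum(
            truth[r.iemg_channel] == (r.force_gauge, r.phase, r.movement)
            for r in table.frame.itertuples()
        )
        print(f"recovered {hits}/{len(table.frame)} ground-truth pairings")
    print(f"pairing table written to {out}")


if __name__ == "__main__":
    main()
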