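#!/usr/bin/env python
"""Aggregate a sweep into the algorithm comparison: best-per-algorithm
rows, median/quartile summaries, and the Friedman + Bonferroni pairwise
significance matrices for both metrics.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from iemgprop import evaluate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=None,
                    help="sweep CSV (default results/sweep_<seed>.csv)")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    results_path = args.results or Path("results") / f"sweep_{args.seed}.csv"

    results = pd.read_csv(results_path)
    best = evaluate.best_per_algorithm(results)
    summary = evaluate.summarize(best)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    best.to_csv(args.out_dir / "best_per_algorithm.csv", index=False)
    summary.to_csv(args.out_dir / "summary.csv", index=False)
    with open(args.out_dir / "summary.json", "w") as fh:
        json.dump(summary.to_dict(orient="records"), fh, indent=2)

    print("best-per-algorithm medians (RMSE % / Pearson r):")
    for row in summary.itertuples():
        print(f"  {row.algorithm:7s} {row.rmse_percent_median:6.1f} %   "
              f"r = {row.pearson_r_median:5.3f}   (n = {row.n})")

    for metric in ("rmse_percent", "pearson_r"):
        wide = best.pivot_table(index="segment_id", columns="algorithm",
                                values=metric).dropna(axis=0)
        if wide.shape[0] < 3:
            print(f"too few complete blocks for the {metric} Friedman test")
            continue
        table = evaluate.friedman_bonferroni(wide.to_numpy(),
                                             algorithms=tuple(wide.columns))
        table.to_frame().to_csv(args.out_dir / f"comparison_{metric}.csv")
        print(f"{metric}: Friedman chi2 = {table.statistic:.1f}, "
              f"p = {table.p_omnibus:.2e}; "
              f"{len(table.flagged_pairs())} significant pairs after Bonferroni")
    print(f"tables written to {args.out_dir}")


if __name__ == "__main__":
    main()
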