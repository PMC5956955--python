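"""Congruence of RTT regression and least-squares dating on the grid results.

Reads results/grid_results.tsv and computes, per scenario, the
proportional difference between the two methods' paired estimates
((lsd - rtt)/rtt) and the bias (fraction of replicates where the RTT
estimate exceeds the LSD estimate), plus the correlation between
stemminess and absolute standardized error.  Writes
results/method_comparison.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from tipclock import evalstats, io  # noqa: E402


def main() -> int:
    results = Path("results/grid_results.tsv")
    if not results.exists():
        print("run analysis/01_run_grid.py first", file=sys.stderr)
        return 1
    table = pd.read_csv(results, sep="\t")
    wide = table.pivot_table(index=["scenario", "replicate"], columns="method",
                             values="estimate").dropna()
    rows = []
    for scen, cell in wide.groupby(level="scenario"):
        pdiff, bias, _ = evalstats.compare_methods(cell["rtt"], cell["lsd"])
        row = {"scenario": scen, "n_pairs": len(cell),
               "median_prop_diff": float(np.median(pdiff)), "bias_rtt_gt_lsd": bias}
        try:
            r, p = evalstats.stemminess_error_correlation(table, scen, "lsd")
            row |= {"stemminess_error_r": r, "stemminess_error_p": p}
        except ValueError:
            pass
        rows.append(row)
    out = pd.DataFrame(rows)
    io.atomic_write_text("results/method_comparison.tsv",
                         out.to_csv(sep="\t", index=False))
    print(out.round(3).to_string(index=False))
    print("\nmedian_prop_diff near 0 and bias near 0.5 indicate congruent methods")
    return 0


if __name__ == "__main__":
    sys.exit(main())
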