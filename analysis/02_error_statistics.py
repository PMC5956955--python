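"""Hypothesis tests on the grid's standardized errors.

Reads results/grid_results.tsv and reports, per estimation method:
one-sample Wilcoxon tests of the standardized errors against zero (per
scenario), the Kruskal-Wallis test of homogeneity across the 12 scenarios
(d.f. = 11), and Holm-corrected pairwise Mann-Whitney comparisons.
Writes results/wilcoxon_tests.tsv and results/pairwise_mwu_<method>.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd  # noqa: E402

from tipclock import evalstats, io  # noqa: E402


def main() -> int:
    results = Path("results/grid_results.tsv")
    if not results.exists():
        print("run analysis/01_run_grid.py first", file=sys.stderr)
        return 1
    table = pd.read_csv(results, sep="\t")

    wil_rows = []
    for (scen, method), cell in table.groupby(["scenario", "method"]):
        errs = cell["std_error"].dropna()
        try:
            stat, p = evalstats.wilcoxon_vs_zero(errs)
        except ValueError:
            stat, p = float("nan"), float("nan")
        wil_rows.append({"scenario": scen, "method": method, "n": len(errs),
                         "wilcoxon_v": stat, "p": p})
    wil = pd.DataFrame(wil_rows)
    io.atomic_write_text("results/wilcoxon_tests.tsv",
                         wil.to_csv(sep="\t", index=False))
    n_sig = int((wil["p"] < 0.05).sum())
    print(f"Wilcoxon vs zero: {n_sig}/{len(wil)} scenario x method cells "
          "differ significantly from zero error (P < 0.05)")

    for method in sorted(table["method"].unique()):
        h, df, p = evalstats.kruskal_wallis_across_scenarios(table, method)
        print(f"Kruskal-Wallis [{method}]: chi2 = {h:.2f}, d.f. = {df}, P = {p:.3g}")
        mat = evalstats.pairwise_mwu(table, method, correction="holm")
        io.atomic_write_text(f"results/pairwise_mwu_{method}.tsv",
                             mat.to_csv(sep="\t"))
    return 0


if __name__ == "__main__":
    sys.exit(main())
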