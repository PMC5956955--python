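"""Evaluation layer of the simulation study.

Runs the full scenario grid (rate level x rate-variation level x
phylo-temporal clustering) through the simulate -> infer -> estimate ->
diagnose pipeline, and computes the summary statistics used to compare
estimation methods: standardized errors and their rank tests (one-sample
Wilcoxon, Kruskal-Wallis, pairwise Mann-Whitney with Holm correction),
proportion of estimates above the truth, interval-width ratios,
stemminess-error correlations, and cross-method congruence (proportional
difference and bias).
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import diagnostics, estimators, ratesim, seqsim, treesim
from .seqsim import SubstModel
from .treesim import ClusteringLevel, ScenarioConfig

__all__ = [
    "standardized_error",
    "wilcoxon_vs_zero",
    "kruskal_wallis_across_scenarios",
    "pairwise_mwu",
    "proportion_above_true",
    "interval_width_ratio",
    "stemminess_error_correlation",
    "compare_methods",
    "default_grid",
    "run_scenario_grid",
    "summarize_results",
    "RESULT_COLUMNS",
]

logger = logging.getLogger(__name__)

#: fixed column order of the long-format results table
RESULT_COLUMNS = [
    "scenario",
    "mean_rate",
    "variance_fraction",
    "clustering",
    "replicate",
    "method",
    "estimate",
    "true_rate",
    "std_error",
    "stemminess",
    "clustering_rho",
    "clustering_p",
]


def standardized_error(estimate: float, true_rate: float) -> float:
    """(estimated - true) / true: the relative error of a rate estimate."""
    if true_rate <= 0:
        raise ValueError("true_rate must be > 0")
    return (estimate - true_rate) / true_rate


def wilcoxon_vs_zero(errors) -> tuple[float, float]:
    """Two-sided one-sample Wilcoxon signed-rank test against zero."""
    arr = np.asarray(errors, dtype=float)
    arr = arr[arr != 0]
    if arr.size == 0:
        raise ValueError("all values are zero: Wilcoxon test degenerate")
    res = stats.wilcoxon(arr, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis_across_scenarios(
    table: pd.DataFrame, method: str
) -> tuple[float, int, float]:
    """Kruskal-Wallis H over per-scenario standardized errors for one method.

    Returns (H, degrees of freedom = groups - 1, chi-square P).
    """
    sub = table[table["method"] == method]
    groups = [g["std_error"].to_numpy() for _, g in sub.groupby("scenario")]
    groups = [g[~np.isnan(g)] for g in groups]
    groups = [g for g in groups if g.size]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 scenario groups")
    h, p = stats.kruskal(*groups)
    return float(h), len(groups) - 1, float(p)


def pairwise_mwu(
    table: pd.DataFrame, method: str, correction: str = "holm"
) -> pd.DataFrame:
    """All pairwise two-sided Mann-Whitney tests between scenario groups.

    Returns a symmetric P-value matrix (unit diagonal) indexed by scenario
    id; ``correction`` is "holm" (default) or "none".
    """
    if correction not in ("holm", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    sub = table[table["method"] == method]
    names = sorted(sub["scenario"].unique())
    groups = {
        s: sub.loc[sub["scenario"] == s, "std_error"].dropna().to_numpy()
        for s in names
    }
    if len(names) < 2:
        raise ValueError("need at least 2 scenario groups")
    for s, g in groups.items():
        if g.size == 0:
            raise ValueError(f"scenario group {s!r} is empty")
    pairs = list(itertools.combinations(names, 2))
    raw = [
        float(stats.mannwhitneyu(groups[a], groups[b],
                                 alternative="two-sided").pvalue)
        for a, b in pairs
    ]
    if correction == "holm":
        adj = multipletests(raw, method="holm")[1]
    else:
        adj = raw
    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for (a, b), p in zip(pairs, adj):
        mat.loc[a, b] = mat.loc[b, a] = min(float(p), 1.0)
    return mat


def proportion_above_true(table: pd.DataFrame, scenario: str, method: str) -> float:
    """Fraction of a cell's replicate estimates exceeding the true rate."""
    cell = table[(table["scenario"] == scenario) & (table["method"] == method)]
    cell = cell.dropna(subset=["estimate"])
    if cell.empty:
        raise ValueError(f"no records for scenario {scenario!r}, method {method!r}")
    return float((cell["estimate"] > cell["true_rate"]).mean())


def interval_width_ratio(estimate: estimators.RateEstimate, true_rate: float) -> float:
    """Interval width divided by the true rate (uncertainty on the rate scale)."""
    if estimate.interval is None:
        raise ValueError("estimate carries no interval")
    if true_rate <= 0:
        raise ValueError("true_rate must be > 0")
    lo, hi = estimate.interval
    return (hi - lo) / true_rate


def stemminess_error_correlation(
    table: pd.DataFrame, scenario: str, method: str
) -> tuple[float, float]:
    """Pearson correlation of per-replicate stemminess with |standardized error|."""
    cell = table[(table["scenario"] == scenario) & (table["method"] == method)]
    cell = cell.dropna(subset=["std_error", "stemminess"])
    if len(cell) < 3:
        raise ValueError("need at least 3 records")
    x = cell["stemminess"].to_numpy()
    y = np.abs(cell["std_error"].to_numpy())
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation degenerate")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def compare_methods(estimates_x, estimates_y) -> tuple[np.ndarray, float, int]:
    """Congruence of two methods' paired estimates.

    Returns (per-pair proportional differences (y-x)/x, bias = fraction of
    pairs with x > y, number of pairs excluded for zero x).
    """
    x = np.asarray(estimates_x, dtype=float)
    y = np.asarray(estimates_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired lists must have equal length")
    keep = x != 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.warning("excluded %d pairs with zero x estimate", n_excluded)
    x, y = x[keep], y[keep]
    prop_diff = (y - x) / x
    bias = float((x > y).mean()) if x.size else float("nan")
    return prop_diff, bias, n_excluded


# ---------------------------------------------------------------------------
# scenario grid


def default_grid(
    rates=(1e-7, 1e-8),
    variance_fractions=(0.001, 0.01, 0.1),
    clustering_levels=(ClusteringLevel.HIGH, ClusteringLevel.LOW),
    **overrides,
) -> list[ScenarioConfig]:
    """Full cross of rate x rate-variation x clustering (12 scenarios)."""
    return [
        ScenarioConfig(
            mean_rate=r, variance_fraction=v, clustering=c, **overrides
        )
        for r, v, c in itertools.product(rates, variance_fractions, clustering_levels)
    ]


def scenario_id(config: ScenarioConfig) -> str:
    return (
        f"rate{config.mean_rate:g}_v{config.variance_fraction:g}"
        f"_{ClusteringLevel(config.clustering).value}"
    )


def run_replicate(
    config: ScenarioConfig,
    rng_seed: int,
    model: SubstModel | None = None,
    n_perm_clustering: int = 1000,
    methods: tuple[str, ...] = ("rtt", "lsd"),
) -> list[dict]:
    """One replicate of the pipeline; returns one record per method."""
    model = model or SubstModel()
    rng = np.random.default_rng(rng_seed)
    tree, dates = treesim.simulate_genealogy(config, int(rng.integers(2**31)))
    rates = ratesim.assign_branch_rates(
        tree, config.mean_rate, config.variance_fraction, config.seq_length,
        int(rng.integers(2**31)),
    )
    phylogram = ratesim.to_phylogram(tree, rates)
    alignment = seqsim.simulate_alignment(
        phylogram, model, config.seq_length, int(rng.integers(2**31))
    )
    inferred = estimators.infer_phylogram(alignment, model)
    rooted = estimators.find_best_root(inferred, dates)
    stem = diagnostics.stemminess(inferred)
    clus = diagnostics.phylo_temporal_clustering(
        inferred, dates, n_perm=n_perm_clustering,
        rng_seed=int(rng.integers(2**31)),
    )
    records = []
    base = {
        "scenario": scenario_id(config),
        "mean_rate": config.mean_rate,
        "variance_fraction": config.variance_fraction,
        "clustering": ClusteringLevel(config.clustering).value,
        "true_rate": config.mean_rate,
        "stemminess": stem,
        "clustering_rho": clus.rho,
        "clustering_p": clus.p_value,
    }
    for method in methods:
        if method == "rtt":
            est = estimators.rtt_regression(rooted, dates).rate
        elif method == "lsd":
            est = estimators.lsd_estimate(rooted, dates, alignment.n_sites)[0].rate
        else:
            raise ValueError(f"unknown method {method!r}")
        records.append(
            base
            | {
                "method": method,
                "estimate": est,
                "std_error": standardized_error(est, config.mean_rate),
            }
        )
    return records


def run_scenario_grid(
    grid: list[ScenarioConfig] | None = None,
    n_replicates: int = 100,
    rng_seed: int = 0,
    model: SubstModel | None = None,
    n_perm_clustering: int = 1000,
    methods: tuple[str, ...] = ("rtt", "lsd"),
    progress: bool = False,
) -> pd.DataFrame:
    """Run every scenario for ``n_replicates`` replicates; long-format table.

    Per-replicate seeds are spawned deterministically from ``rng_seed``;
    replicate failures are logged and contribute missing records rather
    than aborting the run.
    """
    if grid is None:
        grid = default_grid()
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    root_ss = np.random.SeedSequence(rng_seed)
    scenario_seeds = root_ss.spawn(len(grid))
    rows: list[dict] = []
    for config, sseq in zip(grid, scenario_seeds):
        rep_seeds = sseq.spawn(n_replicates)
        for rep, rseq in enumerate(rep_seeds):
            seed = int(rseq.generate_state(1)[0] % (2**31))
            try:
                recs = run_replicate(
                    config, seed, model=model,
                    n_perm_clustering=n_perm_clustering, methods=methods,
                )
            except Exception as exc:  # noqa: BLE001 - per-replicate failures logged
                logger.warning(
                    "replicate failed (scenario=%s, replicate=%d): %s",
                    scenario_id(config), rep, exc,
                )
                continue
            for r in recs:
                r["replicate"] = rep
                rows.append(r)
        if progress:
            print(f"  done {scenario_id(config)}", flush=True)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def summarize_results(table: pd.DataFrame) -> pd.DataFrame:
    """Per scenario x method: median/IQR of errors, Wilcoxon P, prop. above truth."""
    out = []
    for (scen, method), cell in table.groupby(["scenario", "method"]):
        err = cell["std_error"].dropna().to_numpy()
        if err.size == 0:
            continue
        try:
            _, wp = wilcoxon_vs_zero(err)
        except ValueError:
            wp = float("nan")
        q1, med, q3 = np.percentile(err, [25, 50, 75])
        out.append(
            {
                "scenario": scen,
                "method": method,
                "n": err.size,
                "median_error": med,
                "iqr_error": q3 - q1,
                "wilcoxon_p": wp,
                "prop_above_true": proportion_above_true(table, scen, method),
            }
        )
    return pd.DataFrame(out)
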