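"""Rate estimators: distance/NJ stand-in, RTT rooting and regression, LSD, bootstrap."""

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from conftest import set_ages_from_lengths, tree_from_newick
from tipclock.estimators import (
    DegenerateBootstrapError,
    NoTemporalSpreadError,
    bootstrap_interval,
    find_best_root,
    infer_phylogram,
    lsd_estimate,
    pairwise_distances,
    rtt_regression,
    tn93_distance,
)
from tipclock.ratesim import assign_branch_rates, to_phylogram
from tipclock.seqsim import Alignment, SubstModel, simulate_alignment
from tipclock.treesim import (
    TipDates,
    simulate_serial_coalescent,
    simulate_tip_ages,
)


def _rtt_distances(tree):
    out = {}
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        out[leaf.taxon.label] = d
    return out


def _strict_clock_phylogram(mu, n_tips=12, seed=0):
    dates = simulate_tip_ages(n_tips, 0.5, 50_000, rng_seed=seed)
    tree = simulate_serial_coalescent(dates, 250_000.0, seed + 1)
    phy = to_phylogram(tree, assign_branch_rates(tree, mu, 0.0, 1000, 0))
    return phy, dates


class TestDistances:
    def test_jc_closed_form(self, jc_model):
        """JC-patterned data at 10% mismatch give d = -(3/4) ln(1 - 4p/3).

        Under Jukes-Cantor the 12 ordered mismatch types are equally
        frequent, so a balanced pattern table must yield the JC formula.
        """
        n, p = 12_000, 0.1
        counts = np.full((4, 4), n * p / 12)
        np.fill_diagonal(counts, n * (1 - p) / 4)
        d = tn93_distance(counts, jc_model.pi)
        assert d == pytest.approx(-0.75 * np.log(1 - 4 * p / 3), rel=1e-10)

    def test_saturated_pairs_capped(self, jc_model):
        rngm = np.random.default_rng(0)
        aln = Alignment(
            labels=("x", "y"),
            matrix=rngm.integers(0, 4, size=(2, 2000)).astype(np.int8),
        )
        d = pairwise_distances(aln, jc_model)[0, 1]
        assert np.isfinite(d)

    def test_empty_table_rejected(self, jc_model):
        with pytest.raises(ValueError):
            tn93_distance(np.zeros((4, 4)), jc_model.pi)


class TestInferPhylogram:
    def test_three_taxa_exact_path_lengths(self, jc_model):
        """n=3 NJ is fully determined: pairwise paths equal the distances."""
        rngm = np.random.default_rng(5)
        tree0 = tree_from_newick("((a:0.03,b:0.05):0.02,c:0.06);")
        aln = simulate_alignment(tree0, jc_model, 50_000, 7)
        dm = pairwise_distances(aln, jc_model)
        tree = infer_phylogram(aln, jc_model)
        pdm = tree.phylogenetic_distance_matrix()
        tax = {t.label: t for t in tree.taxon_namespace}
        for i, x in enumerate(aln.labels):
            for j, y in enumerate(aln.labels):
                if i < j:
                    assert pdm.distance(tax[x], tax[y]) == pytest.approx(
                        dm[i, j], abs=1e-9
                    )

    def test_topology_consistency_on_easy_instances(self, mito_model):
        """Long sequences on a 10-tip tree: RF distance 0 in >= 95/100 seeds."""
        hits = 0
        for seed in range(100):
            dates = simulate_tip_ages(10, 0.5, 50_000, rng_seed=seed)
            tt = simulate_serial_coalescent(dates, 250_000.0, seed)
            phy = to_phylogram(tt, assign_branch_rates(tt, 1e-7, 0.0, 1000, 0))
            aln = simulate_alignment(phy, mito_model, 100_000, seed)
            inferred = infer_phylogram(aln, mito_model)
            truth = dendropy.Tree.get(
                data=phy.as_string(schema="newick"),
                schema="newick",
                taxon_namespace=inferred.taxon_namespace,
                preserve_underscores=True,
            )
            truth.is_rooted = False
            inferred.is_rooted = False
            truth.encode_bipartitions()
            inferred.encode_bipartitions()
            if treecompare.symmetric_difference(truth, inferred) == 0:
                hits += 1
        assert hits >= 95

    def test_nonnegative_branch_lengths(self, mito_model):
        dates = simulate_tip_ages(8, 0.5, 50_000, rng_seed=3)
        tt = simulate_serial_coalescent(dates, 250_000.0, 3)
        phy = to_phylogram(tt, assign_branch_rates(tt, 1e-7, 0.1, 500, 1))
        aln = simulate_alignment(phy, mito_model, 500, 2)
        tree = infer_phylogram(aln, mito_model)
        assert all(
            (e.length or 0.0) >= 0
            for e in tree.preorder_edge_iter()
        )

    def test_requires_three_sequences(self, jc_model):
        aln = Alignment(labels=("a", "b"), matrix=np.zeros((2, 10), dtype=np.int8))
        with pytest.raises(ValueError):
            infer_phylogram(aln, jc_model)


class TestFindBestRoot:
    def test_noiseless_recovery(self):
        """A clocklike phylogram rerooted arbitrarily is re-rooted with RSS ~ 0."""
        phy, dates = _strict_clock_phylogram(1e-7, n_tips=10, seed=2)
        derooted = phy.clone(depth=1)
        derooted.deroot()
        rooted = find_best_root(derooted, dates)
        assert rooted.best_root_rss == pytest.approx(0.0, abs=1e-18)
        est = rtt_regression(rooted, dates)
        assert est.rate == pytest.approx(1e-7, rel=1e-6)

    def test_matches_grid_search_oracle(self, mito_model):
        """Closed-form optimum vs physically rerooting at a fine grid."""
        dates = simulate_tip_ages(6, 0.5, 50_000, rng_seed=9)
        tt = simulate_serial_coalescent(dates, 250_000.0, 9)
        phy = to_phylogram(tt, assign_branch_rates(tt, 1e-7, 0.1, 500, 3))
        aln = simulate_alignment(phy, mito_model, 400, 4)
        tree = infer_phylogram(aln, mito_model)
        rooted = find_best_root(tree, dates)

        ages = {l: dates.age(l) for l in dates.entries}
        best_grid = np.inf
        edges = [
            n.edge for n in tree.preorder_node_iter() if n.parent_node is not None
        ]
        for eidx in range(len(edges)):
            b = edges[eidx].length or 0.0
            for frac in np.linspace(0, 1, 101):
                work = tree.clone(depth=1)
                wedges = [
                    n.edge
                    for n in work.preorder_node_iter()
                    if n.parent_node is not None
                ]
                work.reroot_at_edge(
                    wedges[eidx], length1=b * (1 - frac), length2=b * frac
                )
                y = _rtt_distances(work)
                labels = sorted(y)
                yv = np.array([y[l] for l in labels])
                xv = np.array([-ages[l] for l in labels])
                coef = np.polyfit(xv, yv, 1)
                rss = float(np.sum((yv - np.polyval(coef, xv)) ** 2))
                best_grid = min(best_grid, rss)
        assert rooted.best_root_rss <= best_grid + 1e-12

        # and the reported optimum is reproduced by the independent pipeline
        y = _rtt_distances(rooted)
        labels = sorted(y)
        yv = np.array([y[l] for l in labels])
        xv = np.array([-ages[l] for l in labels])
        coef = np.polyfit(xv, yv, 1)
        rss = float(np.sum((yv - np.polyval(coef, xv)) ** 2))
        assert rss == pytest.approx(rooted.best_root_rss, rel=1e-9, abs=1e-15)

    def test_degenerate_star_does_not_crash(self):
        tree = tree_from_newick("(a:1,b:1,c:1,d:1);")
        dates = TipDates({"a": 0.0, "b": 0.0, "c": 0.0, "d": 100.0})
        rooted = find_best_root(tree, dates)
        assert rooted.best_root_rss >= 0

    def test_equal_dates_rejected(self):
        tree = tree_from_newick("((a:1,b:1):1,c:1);")
        with pytest.raises(NoTemporalSpreadError):
            find_best_root(tree, TipDates({"a": 5.0, "b": 5.0, "c": 5.0}))


class TestRTTRegression:
    def test_exact_line_on_strict_clock(self):
        phy, dates = _strict_clock_phylogram(1e-8, n_tips=14, seed=4)
        est = rtt_regression(phy, dates)
        assert est.rate == pytest.approx(1e-8, rel=1e-10)
        assert est.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_two_group_slope_arithmetic(self):
        """Distances differing by 1e-3 between groups 10 years apart: slope 1e-4."""
        tree = tree_from_newick(
            "((a:0.021,b:0.02):0.0,(c:0.021,d:0.02):0.0);"
        )
        dates = TipDates({"a": 10.0, "b": 0.0, "c": 10.0, "d": 0.0})
        # forward times: a,c at -10; b,d at 0; distances 0.021 vs 0.020
        est = rtt_regression(tree, dates)
        assert est.rate == pytest.approx(-1e-4, rel=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        """Slope and intercept equal the explicit normal-equations solution."""
        for _ in range(20):
            n = int(rng.integers(4, 12))
            ages = rng.uniform(0, 1000, size=n)
            ages[0], ages[1] = 0.0, 500.0  # guarantee spread
            dists = rng.uniform(0, 0.1, size=n)
            labels = [f"t{i}" for i in range(n)]
            newick = "(" + ",".join(f"{l}:{float(d)!r}" for l, d in zip(labels, dists)) + ");"
            tree = tree_from_newick(newick)
            dates = TipDates(dict(zip(labels, ages)))
            est = rtt_regression(tree, dates)
            x = -ages
            xc = x - x.mean()
            slope = float(xc @ (dists - dists.mean()) / (xc @ xc))
            intercept = float(dists.mean() - slope * x.mean())
            assert est.rate == pytest.approx(slope, rel=1e-12, abs=1e-18)
            assert est.extras["intercept"] == pytest.approx(
                intercept, rel=1e-12, abs=1e-18
            )

    def test_tip_order_invariance(self):
        phy, dates = _strict_clock_phylogram(1e-7, n_tips=8, seed=6)
        est1 = rtt_regression(phy, dates)
        shuffled = TipDates(dict(reversed(list(dates.entries.items()))))
        est2 = rtt_regression(phy, shuffled)
        assert est1.rate == pytest.approx(est2.rate, rel=1e-12)


def _lsd_bruteforce_3tip(blens, ages, site_count, c=10.0):
    """Exhaustive grid minimizer for the 3-tip rooted LSD objective.

    Tree ((a,b)ab, c)root with branch order [ab, a, b, c]; unknowns are the
    rate r and forward times t_ab, t_root.
    """
    b_ab, b_a, b_b, b_c = blens
    t_a, t_b, t_c = -ages[0], -ages[1], -ages[2]
    w = 1.0 / (np.asarray(blens) + c / site_count)
    r_grid = np.linspace(1e-6, 0.2, 400)
    tab_grid = np.linspace(min(t_a, t_b) - 30, min(t_a, t_b), 400)
    troot_grid = np.linspace(min(t_a, t_b, t_c) - 30, min(t_a, t_b, t_c), 400)
    best = (np.inf, None)
    for r in r_grid:
        tab = tab_grid[:, None]
        troot = troot_grid[None, :]
        mask = tab >= troot
        obj = (
            w[0] * (b_ab - r * (tab - troot)) ** 2
            + w[1] * (b_a - r * (t_a - tab)) ** 2
            + w[2] * (b_b - r * (t_b - tab)) ** 2
            + w[3] * (b_c - r * (t_c - troot)) ** 2
        )
        obj = np.where(mask & (tab <= min(t_a, t_b)) & (troot <= t_c), obj, np.inf)
        k = np.unravel_index(np.argmin(obj), obj.shape)
        if obj[k] < best[0]:
            best = (float(obj[k]), r)
    return best


class TestLSD:
    def test_noiseless_strict_clock_recovery(self):
        phy, dates = _strict_clock_phylogram(1e-7, n_tips=10, seed=1)
        est, dated = lsd_estimate(phy, dates, 15_000)
        assert est.rate == pytest.approx(1e-7, rel=1e-8)
        assert est.rss == pytest.approx(0.0, abs=1e-16)
        # node ages match the generating time-tree
        tt = simulate_serial_coalescent(
            simulate_tip_ages(10, 0.5, 50_000, rng_seed=1), 250_000.0, 2
        )
        assert dated.seed_node.age == pytest.approx(tt.seed_node.age, rel=1e-8)

    def test_three_tip_grid_oracle(self):
        """LSD optimum matches a brute-force grid minimizer on 3 tips."""
        blens = [0.4, 0.9, 0.35, 1.1]
        ages = [0.0, 5.0, 10.0]
        tree = tree_from_newick(
            f"((a:{blens[1]},b:{blens[2]}):{blens[0]},c:{blens[3]});"
        )
        dates = TipDates({"a": ages[0], "b": ages[1], "c": ages[2]})
        est, _ = lsd_estimate(tree, dates, 100)
        grid_obj, grid_r = _lsd_bruteforce_3tip(blens, ages, 100)
        assert est.rss <= grid_obj + 1e-9
        assert est.rate == pytest.approx(grid_r, abs=0.2 / 399)

    def test_four_tip_grid_oracle(self):
        """Same exhaustive check on a balanced 4-tip instance (3 time variables)."""
        b = dict(ab=0.3, cd=0.5, a=0.8, b=0.45, c=0.7, d=0.2)
        tree = tree_from_newick(
            f"((a:{b['a']},b:{b['b']}):{b['ab']},(c:{b['c']},d:{b['d']}):{b['cd']});"
        )
        ages = {"a": 0.0, "b": 4.0, "c": 8.0, "d": 2.0}
        dates = TipDates(ages)
        site_count, c_off = 100, 10.0
        est, _ = lsd_estimate(tree, dates, site_count, c_off)

        w = {k: 1.0 / (v + c_off / site_count) for k, v in b.items()}
        t = {k: -v for k, v in ages.items()}
        n_grid = 90
        r_grid = np.linspace(1e-6, 0.25, n_grid)
        tab = np.linspace(min(t["a"], t["b"]) - 25, min(t["a"], t["b"]), n_grid)
        tcd = np.linspace(min(t["c"], t["d"]) - 25, min(t["c"], t["d"]), n_grid)
        troot = np.linspace(-40, min(t["a"], t["b"], t["c"], t["d"]), n_grid)
        best = np.inf
        A, C, R = np.meshgrid(tab, tcd, troot, indexing="ij")
        feas = (A >= R) & (C >= R)
        for r in r_grid:
            obj = (
                w["ab"] * (b["ab"] - r * (A - R)) ** 2
                + w["cd"] * (b["cd"] - r * (C - R)) ** 2
                + w["a"] * (b["a"] - r * (t["a"] - A)) ** 2
                + w["b"] * (b["b"] - r * (t["b"] - A)) ** 2
                + w["c"] * (b["c"] - r * (t["c"] - C)) ** 2
                + w["d"] * (b["d"] - r * (t["d"] - C)) ** 2
            )
            best = min(best, float(np.where(feas, obj, np.inf).min()))
        assert est.rss <= best + 1e-9

    def test_translation_invariance(self):
        phy, dates = _strict_clock_phylogram(1e-7, n_tips=8, seed=3)
        est1, dated1 = lsd_estimate(phy, dates, 1000)
        shifted = TipDates({k: v + 1000.0 for k, v in dates.entries.items()})
        est2, dated2 = lsd_estimate(phy, shifted, 1000)
        assert est2.rate == pytest.approx(est1.rate, rel=1e-9)
        assert dated2.seed_node.age == pytest.approx(
            dated1.seed_node.age + 1000.0, rel=1e-9
        )

    def test_date_scaling_scales_rate_inversely(self):
        phy, dates = _strict_clock_phylogram(1e-7, n_tips=8, seed=5)
        est1, _ = lsd_estimate(phy, dates, 1000)
        scaled = TipDates({k: 3.0 * v for k, v in dates.entries.items()})
        est2, _ = lsd_estimate(phy, scaled, 1000)
        assert est2.rate == pytest.approx(est1.rate / 3.0, rel=1e-9)

    def test_precedence_constraints_hold(self, mito_model):
        """Estimated chronograms never have a child older than its parent."""
        for seed in range(5):
            dates = simulate_tip_ages(12, 0.5, 50_000, rng_seed=seed)
            tt = simulate_serial_coalescent(dates, 250_000.0, seed)
            phy = to_phylogram(tt, assign_branch_rates(tt, 1e-8, 0.1, 2000, seed))
            aln = simulate_alignment(phy, mito_model, 2000, seed)
            rooted = find_best_root(infer_phylogram(aln, mito_model), dates)
            _, dated = lsd_estimate(rooted, dates, 2000)
            for node in dated.preorder_node_iter():
                if node.parent_node is not None:
                    assert node.parent_node.age >= node.age - 1e-6

    def test_equal_dates_rejected(self):
        tree = tree_from_newick("((a:1,b:1):1,c:2);")
        with pytest.raises(NoTemporalSpreadError):
            lsd_estimate(tree, TipDates({"a": 1.0, "b": 1.0, "c": 1.0}), 100)


class TestBootstrap:
    def test_zero_variation_alignment_degenerate_interval(self, jc_model):
        aln = Alignment(
            labels=("a", "b", "c", "d"),
            matrix=np.zeros((4, 200), dtype=np.int8),
        )
        dates = TipDates({"a": 0.0, "b": 10.0, "c": 20.0, "d": 30.0})
        est = bootstrap_interval(aln, dates, "rtt", n_boot=10, rng_seed=0,
                                 model=jc_model)
        assert est.interval[0] == est.interval[1] == est.rate

    def test_percentile_oracle(self, mito_model):
        """Interval endpoints equal percentiles of the stored replicates."""
        dates = simulate_tip_ages(8, 0.5, 50_000, rng_seed=2)
        tt = simulate_serial_coalescent(dates, 250_000.0, 2)
        phy = to_phylogram(tt, assign_branch_rates(tt, 1e-7, 0.0, 800, 0))
        aln = simulate_alignment(phy, mito_model, 800, 3)
        est = bootstrap_interval(aln, dates, "rtt", n_boot=30, level=0.9,
                                 rng_seed=5, model=mito_model)
        reps = est.extras["replicates"]
        lo, hi = np.percentile(reps, [5, 95])
        assert est.interval == (pytest.approx(lo), pytest.approx(hi))

    def test_coverage_on_strong_signal(self, mito_model):
        """95% intervals cover the true rate in most strong-signal data sets."""
        mu = 1e-7
        covered = 0
        n_sets = 40
        for seed in range(n_sets):
            dates = simulate_tip_ages(8, 0.5, 50_000, rng_seed=seed)
            tt = simulate_serial_coalescent(dates, 250_000.0, seed)
            phy = to_phylogram(tt, assign_branch_rates(tt, mu, 0.0, 2000, 0))
            aln = simulate_alignment(phy, mito_model, 2000, seed)
            est = bootstrap_interval(aln, dates, "rtt", n_boot=40, level=0.95,
                                     rng_seed=seed, model=mito_model)
            if est.interval[0] <= mu <= est.interval[1]:
                covered += 1
        assert covered >= int(0.85 * n_sets)

    def test_invalid_method_rejected(self, jc_model):
        aln = Alignment(labels=("a", "b", "c"), matrix=np.zeros((3, 10), dtype=np.int8))
        with pytest.raises(ValueError):
            bootstrap_interval(aln, TipDates({"a": 0.0, "b": 1.0, "c": 2.0}), "beast")
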