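"""Temporal-signal and sampling-structure diagnostics.

* phylo-temporal clustering: Pearson correlation (rho) between pairwise
  topological distance (edges on the tip-to-tip path) and pairwise sampling
  age difference, with a permutation null obtained by shuffling ages across
  tips (default 1,000 permutations);
* date-randomization test (DRT): the rate estimate from the true dates is
  compared against estimates from date-permuted replicates (default 20);
  criterion CR1 passes when the original point estimate falls outside every
  replicate interval, the stricter CR2 when the original interval is
  disjoint from every replicate interval;
* stemminess: proportion of total tree length in internal branches.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import networkx as nx
import numpy as np

from .estimators import (
    RateEstimate,
    bootstrap_interval,
)
from .seqsim import Alignment, SubstModel
from .treesim import TipDates

__all__ = [
    "ClusteringResult",
    "DRTResult",
    "phylo_temporal_clustering",
    "date_randomization_test",
    "stemminess",
]


@dataclass(frozen=True)
class ClusteringResult:
    """Phylo-temporal clustering statistic and its permutation P-value."""

    rho: float
    p_value: float
    n_permutations: int

    def __post_init__(self):
        if not -1.0 <= self.rho <= 1.0 + 1e-12:
            raise ValueError(f"rho out of range: {self.rho}")


@dataclass(frozen=True)
class DRTResult:
    """Date-randomization test outcome for one data set."""

    original: RateEstimate
    replicates: tuple[RateEstimate, ...]
    cr1_pass: bool
    cr2_pass: bool

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def _pairwise_edge_counts(tree: dendropy.Tree, labels: list[str]) -> np.ndarray:
    """Condensed vector of path edge counts for all tip pairs (labels order)."""
    g = nx.Graph()
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            g.add_edge(id(node), id(node.parent_node))
    tip_ids = {leaf.taxon.label: id(leaf) for leaf in tree.leaf_node_iter()}
    n = len(labels)
    mat = np.zeros((n, n))
    for i, li in enumerate(labels):
        lengths = nx.single_source_shortest_path_length(g, tip_ids[li])
        for j in range(i + 1, n):
            mat[i, j] = lengths[tip_ids[labels[j]]]
    iu = np.triu_indices(n, k=1)
    return mat[iu]


def phylo_temporal_clustering(
    tree: dendropy.Tree,
    dates: TipDates,
    n_perm: int = 1000,
    rng_seed: int | np.random.Generator = 0,
    alternative: str = "two-sided",
) -> ClusteringResult:
    """Permutation test for association of tree distance with sampling-age gap.

    P = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_perm) (two-sided;
    ``alternative="greater"`` uses the signed statistic).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) < 3:
        raise ValueError("need at least 3 tips")
    ages = np.array([dates.age(l) for l in labels])
    if np.ptp(ages) == 0:
        raise ValueError("all sampling ages are equal: clustering undefined")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    topo = _pairwise_edge_counts(tree, labels)
    tc = topo - topo.mean()
    tnorm = float(np.sqrt(tc @ tc))
    iu = np.triu_indices(len(labels), k=1)

    def rho_of(a: np.ndarray) -> float:
        diff = np.abs(a[:, None] - a[None, :])[iu]
        dc = diff - diff.mean()
        denom = tnorm * np.sqrt(dc @ dc)
        if denom == 0:
            return 0.0
        return float(tc @ dc / denom)

    rho_obs = rho_of(ages)
    perm_rhos = np.empty(n_perm)
    for k in range(n_perm):
        perm_rhos[k] = rho_of(rng.permutation(ages))
    if alternative == "two-sided":
        exceed = int(np.sum(np.abs(perm_rhos) >= abs(rho_obs)))
    elif alternative == "greater":
        exceed = int(np.sum(perm_rhos >= rho_obs))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + exceed) / (1 + n_perm)
    return ClusteringResult(rho=rho_obs, p_value=p, n_permutations=n_perm)


def _overlaps(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def date_randomization_test(
    alignment: Alignment,
    dates: TipDates,
    method: str = "lsd",
    n_reps: int = 20,
    level: float = 0.95,
    rng_seed: int | np.random.Generator = 0,
    n_boot: int = 100,
    model: SubstModel | None = None,
    cr1_mode: str = "all",
) -> DRTResult:
    """Date-randomization test with CR1/CR2 temporal-signal criteria.

    The estimator pipeline (with bootstrap interval) runs once on the true
    dates and once per replicate on a uniform permutation of the ages across
    tips.  CR1: original point estimate outside all replicate intervals
    (``cr1_mode="most"`` relaxes to >= 95% of them); CR2: original interval
    disjoint from all replicate intervals.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    original = bootstrap_interval(
        alignment, dates, method, n_boot=n_boot, level=level,
        rng_seed=rng, model=model,
    )
    # the original interval always brackets its point estimate, so that
    # interval disjointness (CR2) entails point exclusion (CR1)
    original.interval = (
        min(original.interval[0], original.rate),
        max(original.interval[1], original.rate),
    )
    labels = list(dates.entries.keys())
    ages = np.array([dates.entries[l] for l in labels])
    reps: list[RateEstimate] = []
    for _ in range(n_reps):
        shuffled = dict(zip(labels, ages[rng.permutation(len(ages))]))
        reps.append(
            bootstrap_interval(
                alignment, TipDates(shuffled), method, n_boot=n_boot,
                level=level, rng_seed=rng, model=model,
            )
        )
    outside = [
        not (r.interval[0] <= original.rate <= r.interval[1]) for r in reps
    ]
    if cr1_mode == "all":
        cr1 = all(outside)
    elif cr1_mode == "most":
        cr1 = np.mean(outside) >= 0.95
    else:
        raise ValueError(f"unknown cr1_mode {cr1_mode!r}")
    cr2 = all(not _overlaps(original.interval, r.interval) for r in reps)
    return DRTResult(
        original=original, replicates=tuple(reps), cr1_pass=cr1, cr2_pass=cr2
    )


def stemminess(tree: dendropy.Tree) -> float:
    """Proportion of total tree length contributed by internal branches."""
    internal = 0.0
    total = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        b = node.edge.length or 0.0
        total += b
        if node.is_internal():
            internal += b
    if total <= 0:
        raise ValueError("tree has zero total length: stemminess undefined")
    return internal / total
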