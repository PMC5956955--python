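"""Serial-coalescent genealogy simulation for heterochronous (tip-dated) samples.

Simulates rooted binary time-trees under a constant-size coalescent
conditioned on tip sampling ages, with optional phylo-temporal clustering
constraints (forcing all, or half of, the present-day samples to form a
monophyletic group) and conditioning of the root age on a fixed target by
rescaling internal node ages.

All ages are in years before present (BP): larger = older.  Branch lengths
of the returned trees are durations in years.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Mapping

import dendropy
import numpy as np

__all__ = [
    "TipDates",
    "ClusteringLevel",
    "ScenarioConfig",
    "ConditioningError",
    "simulate_tip_ages",
    "simulate_serial_coalescent",
    "simulate_clustered_genealogy",
    "condition_root_age",
    "simulate_genealogy",
    "timetree_to_newick",
    "validate_timetree",
]


class ConditioningError(RuntimeError):
    """Raised when root-age conditioning exhausts its rejection budget."""


@dataclass(frozen=True)
class TipDates:
    """Map from tip label to sampling age in years before present."""

    entries: Mapping[str, float]

    def __post_init__(self):
        if len(self.entries) < 2:
            raise ValueError("TipDates requires at least 2 entries")
        for name, age in self.entries.items():
            if age < 0:
                raise ValueError(f"negative age for tip {name!r}: {age}")

    @property
    def labels(self) -> list[str]:
        return list(self.entries.keys())

    def age(self, label: str) -> float:
        return self.entries[label]

    @property
    def max_age(self) -> float:
        return max(self.entries.values())

    def modern_labels(self) -> list[str]:
        return sorted(n for n, a in self.entries.items() if a == 0)


class ClusteringLevel(str, Enum):
    """Degree of phylo-temporal clustering imposed on the genealogy.

    high: all present-day (age 0) tips form a monophyletic group.
    low:  the lexicographically first half of the present-day tips form
          a monophyletic group.
    none: unconstrained serial coalescent.
    """

    HIGH = "high"
    LOW = "low"
    NONE = "none"


@dataclass
class ScenarioConfig:
    """One cell of the simulation grid.

    Defaults reproduce the study conditions: 100 tips, half modern, ancient
    ages uniform on (0, 50,000] years, root fixed at 500,000 years,
    15,000-nt sequences.
    """

    mean_rate: float = 1e-7          # subs/site/year
    variance_fraction: float = 0.01  # of the expected number of substitutions
    clustering: ClusteringLevel = ClusteringLevel.NONE
    n_tips: int = 100
    frac_modern: float = 0.5
    max_ancient_age: float = 50_000.0
    root_age: float = 500_000.0
    seq_length: int = 15_000
    effective_size: float = 250_000.0  # haploid coalescent time units (years)
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.mean_rate <= 0:
            raise ValueError("mean_rate must be > 0")
        if self.variance_fraction < 0:
            raise ValueError("variance_fraction must be >= 0")
        if not 0 <= self.frac_modern <= 1:
            raise ValueError("frac_modern must lie in [0, 1]")
        if self.max_ancient_age >= self.root_age:
            raise ValueError("max_ancient_age must be < root_age")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        self.clustering = ClusteringLevel(self.clustering)


def simulate_tip_ages(
    n_tips: int,
    frac_modern: float,
    max_ancient_age: float,
    rng_seed: int,
) -> TipDates:
    """Draw tip sampling ages: a modern fraction at age 0, the rest uniform.

    Exactly ``round(n_tips * frac_modern)`` tips get age 0 (labels
    ``modern_###``); the remainder get i.i.d. ages uniform on
    ``(0, max_ancient_age]`` (labels ``ancient_###``).  Labels are
    deterministic given the inputs.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not 0 <= frac_modern <= 1:
        raise ValueError("frac_modern must lie in [0, 1]")
    if max_ancient_age <= 0:
        raise ValueError("max_ancient_age must be > 0")
    rng = np.random.default_rng(rng_seed)
    n_modern = int(round(n_tips * frac_modern))
    n_ancient = n_tips - n_modern
    width = max(3, len(str(n_tips)))
    entries: dict[str, float] = {}
    for i in range(n_modern):
        entries[f"modern_{i:0{width}d}"] = 0.0
    # uniform on (0, max]: complement of half-open [0, max)
    ages = max_ancient_age * (1.0 - rng.random(n_ancient))
    for i in range(n_ancient):
        entries[f"ancient_{i:0{width}d}"] = float(ages[i])
    return TipDates(entries)


def _make_tip(taxon_namespace: dendropy.TaxonNamespace, label: str, age: float) -> dendropy.Node:
    node = dendropy.Node(taxon=taxon_namespace.require_taxon(label=label))
    node.age = age
    return node


def _serial_coalescent_nodes(
    pending: list[tuple[float, dendropy.Node]],
    effective_size: float,
    rng: np.random.Generator,
) -> dendropy.Node:
    """Coalesce a set of (entry-age, subtree-root) lineages backward in time.

    Lineages enter when the backward clock passes their entry age; while k
    lineages are active the next coalescence waits Exponential with rate
    k(k-1)/(2N), truncated at the next entry epoch; merging pairs are chosen
    uniformly.  Returns the final root node (with .age set on every node).
    """
    queue = sorted(pending, key=lambda t: (t[0], t[1].taxon.label if t[1].taxon else ""))
    active: list[dendropy.Node] = []
    t = queue[0][0] if queue else 0.0
    i = 0
    while i < len(queue) or len(active) > 1:
        # admit all lineages whose entry age <= t
        while i < len(queue) and queue[i][0] <= t:
            active.append(queue[i][1])
            i += 1
        if len(active) < 2:
            t = queue[i][0]
            continue
        k = len(active)
        rate = k * (k - 1) / (2.0 * effective_size)
        wait = rng.exponential(1.0 / rate)
        if i < len(queue) and t + wait >= queue[i][0]:
            t = queue[i][0]
            continue
        t += wait
        ia, ib = rng.choice(k, size=2, replace=False)
        a, b = active[ia], active[ib]
        parent = dendropy.Node()
        parent.age = t
        parent.add_child(a)
        parent.add_child(b)
        active = [n for j, n in enumerate(active) if j not in (ia, ib)]
        active.append(parent)
    return active[0]


def _finalize_tree(root: dendropy.Node, tns: dendropy.TaxonNamespace) -> dendropy.Tree:
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    _set_edge_lengths_from_ages(tree)
    return tree


def _set_edge_lengths_from_ages(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
        else:
            node.edge.length = node.parent_node.age - node.age


def simulate_serial_coalescent(
    dates: TipDates,
    effective_size: float,
    rng_seed: int | np.random.Generator,
) -> dendropy.Tree:
    """Constant-size coalescent genealogy conditioned on heterochronous tip ages."""
    if effective_size <= 0:
        raise ValueError("effective_size must be > 0")
    if len(dates.entries) < 2:
        raise ValueError("need at least 2 tips")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    tns = dendropy.TaxonNamespace()
    pending = [
        (age, _make_tip(tns, label, age))
        for label, age in sorted(dates.entries.items())
    ]
    root = _serial_coalescent_nodes(pending, effective_size, rng)
    return _finalize_tree(root, tns)


def simulate_clustered_genealogy(
    dates: TipDates,
    level: ClusteringLevel,
    effective_size: float,
    rng_seed: int | np.random.Generator,
) -> dendropy.Tree:
    """Serial coalescent with an optional monophyly constraint on modern tips.

    level=high constrains all age-0 tips to a clade; level=low constrains the
    lexicographically first half of them.  The constrained subset is coalesced
    to its MRCA first, then that MRCA enters the serial coalescent of the
    remaining lineages as a single lineage.
    """
    level = ClusteringLevel(level)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if level is ClusteringLevel.NONE:
        return simulate_serial_coalescent(dates, effective_size, rng)
    modern = dates.modern_labels()
    if level is ClusteringLevel.LOW:
        constrained = modern[: len(modern) // 2]
    else:
        constrained = modern
    if len(constrained) < 2:
        raise ValueError(
            f"clustering level {level.value!r} needs >= 2 modern tips to constrain"
        )
    if effective_size <= 0:
        raise ValueError("effective_size must be > 0")
    tns = dendropy.TaxonNamespace()
    constrained_set = set(constrained)
    sub_pending = [
        (0.0, _make_tip(tns, label, 0.0)) for label in sorted(constrained)
    ]
    clade_root = _serial_coalescent_nodes(sub_pending, effective_size, rng)
    rest = [
        (age, _make_tip(tns, label, age))
        for label, age in sorted(dates.entries.items())
        if label not in constrained_set
    ]
    rest.append((clade_root.age, clade_root))
    root = _serial_coalescent_nodes(rest, effective_size, rng)
    return _finalize_tree(root, tns)


def condition_root_age(
    tree: dendropy.Tree,
    target_root_age: float,
    max_rejections: int = 100,
    rng_resimulate: Callable[[], dendropy.Tree] | None = None,
) -> dendropy.Tree:
    """Fix the root age to a target by rescaling internal node ages.

    Internal ages (measured from the present) are multiplied by
    f = target / current-root-age; tip ages are untouched.  If the rescaled
    tree violates temporal precedence (possible when f < 1), the genealogy
    is rejected and resimulated via ``rng_resimulate``, up to
    ``max_rejections`` times.
    """
    max_tip_age = max(leaf.age for leaf in tree.leaf_node_iter())
    if target_root_age <= max_tip_age:
        raise ValueError("target_root_age must exceed the oldest tip age")
    candidate = tree
    for _ in range(max_rejections + 1):
        f = target_root_age / candidate.seed_node.age
        ok = True
        for node in candidate.preorder_internal_node_iter():
            new_age = node.age * f
            for child in node.child_nodes():
                child_age = child.age * f if child.is_internal() else child.age
                if new_age <= child_age:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            for node in candidate.preorder_internal_node_iter():
                node.age *= f
            candidate.seed_node.age = target_root_age
            _set_edge_lengths_from_ages(candidate)
            return candidate
        if rng_resimulate is None:
            raise ConditioningError(
                "root-age rescaling would make an internal node younger than "
                "a descendant tip, and no resimulation callback was given"
            )
        candidate = rng_resimulate()
    raise ConditioningError(
        f"root-age conditioning failed after {max_rejections} rejections: "
        "rescaled internal nodes kept violating tip-age precedence"
    )


def simulate_genealogy(config: ScenarioConfig, rng_seed: int) -> tuple[dendropy.Tree, TipDates]:
    """One conditioned genealogy under a scenario: ages, coalescent, clustering, root fix."""
    rng = np.random.default_rng(rng_seed)
    dates = simulate_tip_ages(
        config.n_tips, config.frac_modern, config.max_ancient_age,
        rng.integers(2**31),
    )

    def _draw() -> dendropy.Tree:
        return simulate_clustered_genealogy(
            dates, config.clustering, config.effective_size,
            np.random.default_rng(rng.integers(2**31)),
        )

    tree = condition_root_age(_draw(), config.root_age, max_rejections=1000,
                              rng_resimulate=_draw)
    return tree, dates


def validate_timetree(tree: dendropy.Tree, dates: TipDates | None = None) -> None:
    """Assert structural validity: parent older than child; tip ages as given."""
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.parent_node.age <= node.age:
            raise AssertionError(
                f"parent age {node.parent_node.age} <= child age {node.age}"
            )
    if dates is not None:
        for leaf in tree.leaf_node_iter():
            expected = dates.age(leaf.taxon.label)
            if leaf.age != expected:
                raise AssertionError(
                    f"tip {leaf.taxon.label}: age {leaf.age} != given {expected}"
                )


def timetree_to_newick(tree: dendropy.Tree) -> str:
    """Newick serialization with branch lengths in years (12 sig. digits)."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".12g",
    ).strip() + "\n"
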