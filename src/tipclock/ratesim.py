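"""White-noise branch-rate assignment and conversion of time-trees to phylograms.

Under a white-noise clock, each branch gets an independent rate whose
variance is inversely proportional to the branch duration, calibrated so
that the variance of the expected substitution count on a branch equals a
fixed fraction v of its expectation:

    n_i = r_i * d_i * L,   Var(n_i) = v * E[n_i]
    =>  Var(r_i) = v * mu / (d_i * L)

where d_i is the branch duration in years and L the sequence length.  Rates
are drawn from a Gamma distribution matching this mean and variance (always
positive).  An alternative constant-CV reading, Var(r_i) = v * mu^2, is
available via ``mode="rate_cv"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np

__all__ = ["BranchRates", "assign_branch_rates", "to_phylogram"]


@dataclass(frozen=True)
class BranchRates:
    """Per-edge substitution rates (subs/site/year), keyed by child-node id."""

    rates: Mapping[int, float]
    mean_rate: float

    def rate_for(self, node: dendropy.Node) -> float:
        return self.rates[id(node)]


def assign_branch_rates(
    tree: dendropy.Tree,
    mean_rate: float,
    variance_fraction: float,
    seq_length: int,
    rng_seed: int | np.random.Generator,
    mode: str = "white_noise",
) -> BranchRates:
    """Draw one rate per edge from a Gamma with the white-noise variance law.

    variance_fraction = 0 returns the constant rate ``mean_rate`` on every
    edge (strict clock).
    """
    if mean_rate <= 0:
        raise ValueError("mean_rate must be > 0")
    if variance_fraction < 0:
        raise ValueError("variance_fraction must be >= 0")
    if mode not in ("white_noise", "rate_cv"):
        raise ValueError(f"unknown rate-variation mode {mode!r}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    rates: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        duration = node.parent_node.age - node.age
        if duration <= 0:
            raise ValueError("branch durations must be > 0")
        if variance_fraction == 0:
            rates[id(node)] = mean_rate
            continue
        if mode == "white_noise":
            var = variance_fraction * mean_rate / (duration * seq_length)
        else:  # constant coefficient of variation
            var = variance_fraction * mean_rate**2
        shape = mean_rate**2 / var
        scale = var / mean_rate
        rates[id(node)] = float(rng.gamma(shape, scale))
    return BranchRates(rates=rates, mean_rate=mean_rate)


def to_phylogram(tree: dendropy.Tree, rates: BranchRates) -> dendropy.Tree:
    """True phylogram: same topology, edge length b_i = r_i * duration_i (subs/site)."""
    phylo = tree.clone(depth=1)
    # clone(1) copies nodes, so walk the two trees in parallel preorder
    for src, dst in zip(tree.preorder_node_iter(), phylo.preorder_node_iter()):
        if src.parent_node is None:
            dst.edge.length = None
            continue
        if id(src) not in rates.rates:
            raise ValueError("rates missing an edge present in the tree")
        duration = src.parent_node.age - src.age
        dst.edge.length = rates.rates[id(src)] * duration
    return phylo
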