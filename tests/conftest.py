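import dendropy
import numpy as np
import pytest

from tipclock.seqsim import SubstModel
from tipclock.treesim import TipDates


@pytest.fixture
def jc_model() -> SubstModel:
    """Jukes-Cantor limit of HKY: kappa=1, uniform frequencies, no gamma."""
    return SubstModel(kappa=1.0, freqs=(0.25, 0.25, 0.25, 0.25), alpha=None)


@pytest.fixture
def mito_model() -> SubstModel:
    return SubstModel()


@pytest.fixture
def four_tip_dates() -> TipDates:
    return TipDates({"a": 0.0, "b": 0.0, "c": 10_000.0, "d": 30_000.0})


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def set_ages_from_lengths(tree: dendropy.Tree, dates: TipDates) -> dendropy.Tree:
    """Attach .age to all nodes of a time-tree whose lengths are in years."""
    for leaf in tree.leaf_node_iter():
        leaf.age = dates.age(leaf.taxon.label)
    for node in tree.postorder_internal_node_iter():
        child = node.child_nodes()[0]
        node.age = child.age + (child.edge.length or 0.0)
    return tree


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
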