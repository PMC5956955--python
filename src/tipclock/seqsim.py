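"""Sequence simulation along a phylogram under HKY85 with discrete-gamma rates.

The HKY generator is built with transition/transversion ratio kappa and
stationary frequencies pi, normalized so branch lengths are in expected
substitutions per site.  Among-site rate variation uses the standard
discrete-gamma approximation: n equal-probability categories, each
represented by its conditional mean rate, normalized to overall mean 1;
the category of a site is i.i.d. across sites and fixed across the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

__all__ = [
    "SubstModel",
    "Alignment",
    "hky_rate_matrix",
    "transition_probabilities",
    "gamma_category_rates",
    "simulate_alignment",
]

NUCLEOTIDES = "ACGT"
# index: A=0, C=1, G=2, T=3; transitions are A<->G and C<->T
_TRANSITION = np.zeros((4, 4), dtype=bool)
for _x, _y in ((0, 2), (2, 0), (1, 3), (3, 1)):
    _TRANSITION[_x, _y] = True


@dataclass(frozen=True)
class SubstModel:
    """HKY + discrete-gamma substitution model parameters.

    Defaults are typical of vertebrate mitogenomes: strong transition bias
    (kappa = 10), AC-rich composition, and substantial among-site rate
    heterogeneity (alpha = 0.5).
    """

    kappa: float = 10.0
    freqs: tuple[float, float, float, float] = (0.31, 0.31, 0.13, 0.25)
    alpha: float | None = 0.5  # None disables among-site variation
    n_categories: int = 4

    def __post_init__(self):
        pi = np.asarray(self.freqs, dtype=float)
        if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("freqs must be 4 positive values summing to 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")

    @property
    def pi(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=float)


@dataclass(frozen=True)
class Alignment:
    """Equal-length nucleotide sequences keyed by tip label (order preserved)."""

    labels: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)  # (n_taxa, n_sites) int8 codes 0..3

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.labels):
            raise ValueError("matrix shape must be (n_labels, n_sites)")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, label: str) -> str:
        row = self.matrix[self.labels.index(label)]
        return "".join(NUCLEOTIDES[c] for c in row)

    def to_fasta(self, width: int = 80) -> str:
        chunks = []
        for i, label in enumerate(self.labels):
            seq = "".join(NUCLEOTIDES[c] for c in self.matrix[i])
            chunks.append(f">{label}")
            chunks.extend(seq[j : j + width] for j in range(0, len(seq), width))
        return "\n".join(chunks) + "\n"

    @classmethod
    def from_fasta(cls, text: str) -> "Alignment":
        labels: list[str] = []
        seqs: list[str] = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                labels.append(line[1:].split()[0])
                seqs.append("")
            else:
                seqs[-1] += line.upper()
        if not labels:
            raise ValueError("no sequences in FASTA input")
        lut = np.full(128, -1, dtype=np.int8)
        for i, c in enumerate(NUCLEOTIDES):
            lut[ord(c)] = i
        mat = np.array(
            [lut[np.frombuffer(s.encode(), dtype=np.uint8)] for s in seqs],
            dtype=np.int8,
        )
        if np.any(mat < 0):
            raise ValueError("non-ACGT character in alignment")
        return cls(labels=tuple(labels), matrix=mat)


def hky_rate_matrix(model: SubstModel) -> np.ndarray:
    """HKY generator Q, normalized to one expected substitution per unit length.

    Off-diagonals: q_xy = kappa * pi_y for transitions, pi_y for
    transversions; rows sum to zero; scaled so -sum_x pi_x q_xx = 1.
    """
    pi = model.pi
    q = np.where(_TRANSITION, model.kappa, 1.0) * pi[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -(pi * np.diag(q)).sum()
    return q / mu


def transition_probabilities(model: SubstModel, branch_length: float) -> np.ndarray:
    """P(b) = expm(Q b); a proper stochastic matrix for any b >= 0."""
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    return expm(hky_rate_matrix(model) * branch_length)


def gamma_category_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean rates of equal-probability discrete-gamma categories, mean exactly 1.

    Category k's rate is E[X | q_k < X <= q_{k+1}] for X ~ Gamma(alpha,
    scale 1/alpha), computed from the partial expectation of the gamma.
    """
    if n_categories == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(
        np.linspace(0, 1, n_categories + 1), a=alpha, scale=1.0 / alpha
    )
    # E[X; X <= x] for Gamma(a, 1/a) equals CDF of Gamma(a+1, 1/a) at x
    partial = gamma_dist.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
    rates = np.diff(partial) * n_categories
    return rates / rates.mean()


def simulate_alignment(
    tree: dendropy.Tree,
    model: SubstModel,
    seq_length: int,
    rng_seed: int | np.random.Generator,
) -> Alignment:
    """Evolve sequences down a phylogram (branch lengths in subs/site).

    The root sequence is drawn from pi; each site carries one gamma
    category; each edge applies P(b_i * category_rate).  Deterministic for
    a given seed.
    """
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")

    if model.alpha is None:
        cat_rates = np.ones(1)
    else:
        cat_rates = gamma_category_rates(model.alpha, model.n_categories)
    site_cat = rng.integers(len(cat_rates), size=seq_length)

    q = hky_rate_matrix(model)
    evals, evecs = np.linalg.eig(q)
    inv_evecs = np.linalg.inv(evecs)

    def pmatrix(b: float) -> np.ndarray:
        p = np.clip(((evecs * np.exp(evals * b)) @ inv_evecs).real, 0.0, 1.0)
        return p / p.sum(axis=1, keepdims=True)

    root_seq = rng.choice(4, size=seq_length, p=model.pi).astype(np.int8)
    seqs: dict[str, np.ndarray] = {}
    states = {id(tree.seed_node): root_seq}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            parent_state = states[id(node.parent_node)]
            b = node.edge.length or 0.0
            child_state = np.empty(seq_length, dtype=np.int8)
            for ci, crate in enumerate(cat_rates):
                mask = site_cat == ci
                if not mask.any():
                    continue
                p = pmatrix(b * crate)
                cum = np.cumsum(p, axis=1)
                u = rng.random(int(mask.sum()))
                rows = cum[parent_state[mask]]
                child_state[mask] = np.minimum((u[:, None] > rows).sum(axis=1), 3)
            states[id(node)] = child_state
        if node.is_leaf():
            seqs[node.taxon.label] = states[id(node)]
    return Alignment(labels=tuple(labels), matrix=np.array([seqs[l] for l in labels]))
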