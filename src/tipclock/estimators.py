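"""Substitution-rate estimators for tip-dated phylograms.

Two estimators are provided, mirroring the two standard fast alternatives
to Bayesian tip dating:

* root-to-tip (RTT) regression: ordinary least squares of root-to-tip
  distance (subs/site) on sampling time, with the root placed at the
  position on the tree that minimizes the residual sum of squares (the
  objective used by TempEst-style rooting);
* least-squares dating (LSD): a strict-clock weighted least-squares fit of
  branch lengths to rate x duration over the rate and the internal node
  times, with tip times fixed at their sampling dates and temporal
  precedence enforced on every edge (the Langley-Fitch normal
  approximation).

A neighbor-joining tree on closed-form TN93 distances serves as the
phylogram-inference stand-in; externally inferred phylograms can be
supplied instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import networkx as nx
import numpy as np
from scipy import stats
from scipy.optimize import minimize
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .seqsim import Alignment, SubstModel
from .treesim import TipDates

__all__ = [
    "RateEstimate",
    "NoTemporalSpreadError",
    "DegenerateBootstrapError",
    "pairwise_distances",
    "infer_phylogram",
    "find_best_root",
    "rtt_regression",
    "lsd_estimate",
    "bootstrap_interval",
]

logger = logging.getLogger(__name__)


class NoTemporalSpreadError(ValueError):
    """All sampling dates identical: the rate is not identifiable."""


class DegenerateBootstrapError(RuntimeError):
    """Too many bootstrap replicates failed to produce an estimate."""


@dataclass
class RateEstimate:
    """A method-tagged point estimate of the substitution rate.

    rate is in subs/site/year.  interval, when present, is a
    (lower, upper) percentile interval at confidence ``level``.
    """

    method: str
    rate: float
    interval: tuple[float, float] | None = None
    level: float | None = None
    r_squared: float | None = None
    tmrca_age_bp: float | None = None
    rss: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.interval is not None:
            lo, hi = self.interval
            if not (lo <= self.rate <= hi):
                logger.warning(
                    "interval (%g, %g) does not bracket point estimate %g",
                    lo, hi, self.rate,
                )


# ---------------------------------------------------------------------------
# phylogram inference (ML tree-search stand-in): TN93 distances + neighbor joining


def _pair_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """4x4 site-pattern count table between two coded sequences."""
    return np.bincount(4 * a.astype(np.int64) + b, minlength=16).reshape(4, 4)


def tn93_distance(
    counts: np.ndarray,
    pi: np.ndarray,
    max_distance: float = 5.0,
    alpha: float | None = None,
) -> float:
    """Closed-form TN93 evolutionary distance from a 4x4 mismatch table.

    Uses the supplied stationary frequencies; ``alpha`` applies the
    standard gamma-rates correction (-ln w -> alpha (w^{-1/alpha} - 1)).
    Saturated comparisons (log argument <= 0) are capped at
    ``max_distance``.  With kappa = 1 and uniform frequencies this reduces
    to the Jukes-Cantor formula.
    """
    n = counts.sum()
    if n == 0:
        raise ValueError("empty pattern table")
    p1 = (counts[0, 2] + counts[2, 0]) / n  # A<->G transitions
    p2 = (counts[1, 3] + counts[3, 1]) / n  # C<->T transitions
    q = (counts.sum() - np.trace(counts)
         - counts[0, 2] - counts[2, 0] - counts[1, 3] - counts[3, 1]) / n
    pi_a, pi_c, pi_g, pi_t = pi
    pi_r = pi_a + pi_g
    pi_y = pi_c + pi_t
    k1 = 2 * pi_a * pi_g / pi_r
    k2 = 2 * pi_c * pi_t / pi_y
    k3 = 2 * (pi_r * pi_y - pi_a * pi_g * pi_y / pi_r - pi_c * pi_t * pi_r / pi_y)
    w1 = 1 - p1 / k1 - q / (2 * pi_r)
    w2 = 1 - p2 / k2 - q / (2 * pi_y)
    w3 = 1 - q / (2 * pi_r * pi_y)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return max_distance
    if alpha is None:
        h1, h2, h3 = -np.log(w1), -np.log(w2), -np.log(w3)
    else:
        h1 = alpha * (w1 ** (-1.0 / alpha) - 1.0)
        h2 = alpha * (w2 ** (-1.0 / alpha) - 1.0)
        h3 = alpha * (w3 ** (-1.0 / alpha) - 1.0)
    d = k1 * h1 + k2 * h2 + k3 * h3
    return float(min(max(d, 0.0), max_distance))


def pairwise_distances(alignment: Alignment, model: SubstModel) -> np.ndarray:
    """Symmetric matrix of TN93 distances between all sequence pairs."""
    n = len(alignment.labels)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            c = _pair_counts(alignment.matrix[i], alignment.matrix[j])
            dm[i, j] = dm[j, i] = tn93_distance(c, model.pi, alpha=model.alpha)
    return dm


def infer_phylogram(alignment: Alignment, model: SubstModel) -> dendropy.Tree:
    """Neighbor-joining phylogram on pairwise TN93 distances (unrooted).

    Negative NJ branch lengths are clamped to zero.  An alignment with no
    variation yields a star-like tree with zero lengths (warning logged).
    """
    if len(alignment.labels) < 3:
        raise ValueError("need at least 3 sequences")
    dm = pairwise_distances(alignment, model)
    if not dm.any():
        logger.warning("alignment has no variation; tree is star-like with zero lengths")
    sk_tree = _skbio_nj(DistanceMatrix(dm, ids=list(alignment.labels)), neg_as_zero=True)
    tree = dendropy.Tree.get(
        data=str(sk_tree).strip(), schema="newick",
        preserve_underscores=True,
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# RTT rooting and regression


def _tip_node_distances(tree: dendropy.Tree) -> dict[str, dict[int, float]]:
    """Path length (sum of branch lengths) from every tip to every node."""
    g = nx.Graph()
    for node in tree.preorder_node_iter():
        g.add_node(id(node))
        if node.parent_node is not None:
            g.add_edge(id(node), id(node.parent_node), weight=node.edge.length or 0.0)
    out: dict[str, dict[int, float]] = {}
    for leaf in tree.leaf_node_iter():
        out[leaf.taxon.label] = nx.single_source_dijkstra_path_length(
            g, id(leaf), weight="weight"
        )
    return out


def find_best_root(tree: dendropy.Tree, dates: TipDates) -> dendropy.Tree:
    """Root the phylogram at the point minimizing the RTT regression RSS.

    For each edge the RTT distances are affine in the root position, so the
    RSS is an exactly minimizable quadratic; the global (edge, position)
    optimum is taken, ties broken by preorder edge index.  Returns a new
    rooted tree (the input is not modified).
    """
    tree = tree.clone(depth=1)
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise ValueError("need at least 3 tips to optimize the root")
    ages = np.array([dates.age(l) for l in leaves])
    x = -ages
    if np.ptp(x) == 0:
        raise NoTemporalSpreadError("all sampling dates are identical")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    dist = _tip_node_distances(tree)

    best = None  # (rss, preorder_index, edge, s)
    for idx, node in enumerate(tree.preorder_node_iter()):
        if node.parent_node is None:
            continue
        b = node.edge.length or 0.0
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        y0 = np.array(
            [
                dist[l][id(node)] if l in below else dist[l][id(node.parent_node)] + b
                for l in leaves
            ]
        )
        sgn = np.array([1.0 if l in below else -1.0 for l in leaves])
        y0c = y0 - y0.mean()
        sc = sgn - sgn.mean()
        a_ = float(y0c @ y0c)
        b_ = float(y0c @ sc)
        c_ = float(sc @ sc)
        d_ = float(xc @ y0c)
        e_ = float(xc @ sc)
        # RSS(s) = a + 2 b s + c s^2 - (d + e s)^2 / sxx
        qa = c_ - e_ * e_ / sxx
        qb = b_ - d_ * e_ / sxx
        candidates = [0.0, b]
        if qa > 1e-30:
            candidates.append(float(np.clip(-qb / qa, 0.0, b)))
        for s in candidates:
            rss = a_ + 2 * b_ * s + c_ * s * s - (d_ + e_ * s) ** 2 / sxx
            key = (rss, idx, s)
            if best is None or key < (best[0], best[1], best[3]):
                best = (rss, idx, node.edge, s)
    rss, _, edge, s = best
    b = edge.length or 0.0
    # dendropy assigns length1 to the old-parent side, length2 to the child side
    tree.reroot_at_edge(edge, length1=b - s, length2=s, update_bipartitions=False)
    tree.best_root_rss = max(rss, 0.0)
    return tree


def rtt_regression(tree: dendropy.Tree, dates: TipDates) -> RateEstimate:
    """OLS of root-to-tip distance on sampling time; slope is the rate.

    A negative slope is returned as-is (with a warning): absence of
    temporal signal is a result, not an error.
    """
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise ValueError("need at least 2 tips")
    y = []
    for leaf in leaves:
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        y.append(d)
    y = np.array(y)
    x = np.array([-dates.age(leaf.taxon.label) for leaf in leaves])
    if np.ptp(x) == 0:
        raise NoTemporalSpreadError("all sampling dates are identical")
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    if slope <= 0:
        logger.warning("RTT regression slope is non-positive (%g)", slope)
        tmrca = None
    else:
        tmrca = intercept / slope
    rss = float(np.sum((y - (intercept + slope * x)) ** 2))
    return RateEstimate(
        method="rtt",
        rate=slope,
        r_squared=float(res.rvalue**2),
        tmrca_age_bp=tmrca,
        rss=rss,
        extras={"intercept": intercept},
    )


# ---------------------------------------------------------------------------
# least-squares dating


def lsd_estimate(
    tree: dendropy.Tree,
    dates: TipDates,
    site_count: int,
    variance_offset_c: float = 10.0,
) -> tuple[RateEstimate, dendropy.Tree]:
    """Strict-clock least-squares dating of a rooted phylogram.

    Minimizes sum_i w_i (b_i - r (tau_child - tau_parent))^2 over the rate
    r > 0 and internal forward-times tau, with tips fixed at tau = -age and
    tau_child >= tau_parent on every edge; w_i = 1/(b_i + c/s).  With the
    substitution u_v = r tau_v for internal v, the problem is a convex
    quadratic program in (u, r), solved exactly by weighted linear least
    squares when the unconstrained optimum is feasible and by a
    trust-region constrained quadratic solve otherwise.

    Returns the rate estimate and a dated copy of the tree with estimated
    node ages (years BP) on every node.
    """
    if variance_offset_c <= 0:
        raise ValueError("variance_offset_c must be > 0")
    tree = tree.clone(depth=1)
    leaves = list(tree.leaf_node_iter())
    tip_tau = {id(l): -dates.age(l.taxon.label) for l in leaves}
    if len({dates.age(l.taxon.label) for l in leaves}) < 2:
        raise NoTemporalSpreadError("all sampling dates are identical")

    internal = [n for n in tree.preorder_node_iter() if n.is_internal()]
    index = {id(n): i for i, n in enumerate(internal)}
    m = len(internal)  # variables: u_0..u_{m-1}, r at position m
    edges = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
    n_e = len(edges)
    amat = np.zeros((n_e, m + 1))
    bvec = np.empty(n_e)
    w = np.empty(n_e)
    for i, child in enumerate(edges):
        b = child.edge.length or 0.0
        bvec[i] = b
        w[i] = 1.0 / (b + variance_offset_c / site_count)
        amat[i, index[id(child.parent_node)]] = -1.0
        if child.is_leaf():
            amat[i, m] = tip_tau[id(child)]
        else:
            amat[i, index[id(child)]] = 1.0
    sw = np.sqrt(w)

    # precedence constraints:  u_child - u_parent >= 0  (tip rows use r*tau_tip)
    rrow = np.zeros((1, m + 1))
    rrow[0, m] = 1.0
    cmat = np.vstack([amat, rrow])  # precedence rows plus r >= 0
    cons_lb = np.zeros(n_e + 1)

    z, *_ = np.linalg.lstsq(sw[:, None] * amat, sw * bvec, rcond=None)
    if np.all(cmat @ z >= cons_lb - 1e-12 * max(1.0, float(np.abs(bvec).max()))):
        sol = z
    else:
        sol = _constrained_lsd(amat, bvec, w, cmat)

    r = float(max(sol[m], 1e-15))
    dated = tree
    for node in dated.preorder_node_iter():
        if node.is_leaf():
            node.age = dates.age(node.taxon.label)
        else:
            node.age = -float(sol[index[id(node)]]) / r
    # exact precedence: absorb solver round-off into the parent age
    for node in dated.postorder_node_iter():
        if node.is_internal():
            node.age = max(node.age, max(c.age for c in node.child_nodes()))
    for node in dated.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age - node.age
    resid = amat @ sol - bvec
    rss = float(w @ resid**2)
    est = RateEstimate(
        method="lsd",
        rate=r,
        tmrca_age_bp=float(dated.seed_node.age),
        rss=rss,
    )
    return est, dated


def _constrained_lsd(amat: np.ndarray, bvec: np.ndarray, w: np.ndarray,
                     cmat: np.ndarray) -> np.ndarray:
    """Solve the LSD quadratic program when precedence constraints bind.

    The primal  min_z ||sqrt(w) (A z - b)||^2  s.t.  C z >= 0  is strictly
    convex, so it is solved through its Lagrangian dual
        max_{lam >= 0}  -(1/2) (C' lam - g)' H^{-1} (C' lam - g)
    with H = 2 A' W A and g = -2 A' W b — a bound-constrained smooth
    quadratic handled by L-BFGS-B — and the primal solution recovered as
    z = H^{-1} (C' lam - g), which is feasible at the dual optimum.
    """
    h = 2.0 * (amat.T * w) @ amat
    g = -2.0 * (amat.T * w) @ bvec
    try:
        h_inv = np.linalg.inv(h)
    except np.linalg.LinAlgError:
        h_inv = np.linalg.pinv(h)
    q = cmat @ h_inv @ cmat.T
    d = cmat @ h_inv @ g

    def dual(lam: np.ndarray):
        grad = q @ lam - d
        return 0.5 * float(lam @ q @ lam) - float(lam @ d), grad

    res = minimize(
        dual, np.zeros(cmat.shape[0]), jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * cmat.shape[0],
        options={"maxiter": 20000, "ftol": 1e-18, "gtol": 1e-14},
    )
    return h_inv @ (cmat.T @ res.x - g)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_interval(
    alignment: Alignment,
    dates: TipDates,
    method: str,
    n_boot: int = 100,
    level: float = 0.95,
    rng_seed: int | np.random.Generator = 0,
    model: SubstModel | None = None,
    variance_offset_c: float = 10.0,
) -> RateEstimate:
    """Nonparametric (site-resampling) bootstrap interval for a rate estimate.

    Resamples alignment columns with replacement and re-runs the full
    estimation pipeline (distance tree, RTT-optimal root, estimator) per
    replicate; returns the original-data point estimate with a percentile
    interval.  Replicate estimates are kept in ``extras['replicates']``.
    """
    if method not in ("rtt", "lsd"):
        raise ValueError(f"unknown method {method!r}")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    model = model or SubstModel()

    def run(aln: Alignment) -> float:
        rooted = find_best_root(infer_phylogram(aln, model), dates)
        if method == "rtt":
            return rtt_regression(rooted, dates).rate
        return lsd_estimate(rooted, dates, aln.n_sites, variance_offset_c)[0].rate

    point = run(alignment)
    reps: list[float] = []
    failures = 0
    for _ in range(n_boot):
        cols = rng.integers(alignment.n_sites, size=alignment.n_sites)
        baln = Alignment(labels=alignment.labels, matrix=alignment.matrix[:, cols])
        try:
            reps.append(run(baln))
        except Exception:  # noqa: BLE001 - replicate failures are tolerated
            failures += 1
    if failures > n_boot / 2:
        raise DegenerateBootstrapError(
            f"{failures}/{n_boot} bootstrap replicates failed"
        )
    lo, hi = np.percentile(reps, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return RateEstimate(
        method=method,
        rate=point,
        interval=(float(lo), float(hi)),
        level=level,
        extras={"replicates": reps, "n_failures": failures},
    )
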