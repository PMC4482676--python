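"""Phylogenetic structure tests for continuous fruit traits.

Builds a framework (taxonomy-based) species-level tree, optimizes each
trait onto it under linear (Farris) parsimony to obtain steps and the
consistency/retention indices, and runs the two standard model-based
phylogenetic signal tests: Blomberg's K with a tip-randomization p-value
and Pagel's lambda with a likelihood-ratio test against the
no-signal (lambda = 0) null.

The framework tree is a nested set of polytomies — orders at the root,
families within orders, genera within families, species as tips — with
unit branch lengths, mirroring how a classification is used as a stand-in
phylogeny when no molecular tree is available.  Species whose family and
order are unknown attach directly to the root polytomy.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .traits import SpeciesTraitRecord

__all__ = [
    "UNKNOWN_TAXON",
    "SignalStatistics",
    "tree_from_taxonomy",
    "phylo_covariance",
    "parsimony_steps_continuous",
    "ci_ri",
    "blomberg_k",
    "pagel_lambda",
    "signal_table",
]

#: Marker used in trait tables for unknown family/order assignments.
UNKNOWN_TAXON = "UK"


def genus_of(species: str) -> str:
    """Genus label: the first whitespace-delimited token of the species name."""
    return species.split()[0]


def tree_from_taxonomy(records: Sequence[SpeciesTraitRecord]) -> dendropy.Tree:
    """Build the framework tree from order/family/genus/species nesting.

    Orders form a polytomy at the root, families nest within orders and
    genera within families; all branch lengths are 1.  Species with
    unknown placement (family or order equal to ``"UK"``) attach directly
    to the root polytomy.
    """
    seen: set[str] = set()
    for rec in records:
        if rec.species in seen:
            raise ValueError(f"duplicate species label {rec.species!r}")
        seen.add(rec.species)

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    order_nodes: dict[str, dendropy.Node] = {}
    family_nodes: dict[tuple[str, str], dendropy.Node] = {}
    genus_nodes: dict[tuple[str, str, str], dendropy.Node] = {}

    def _child(parent: dendropy.Node) -> dendropy.Node:
        node = dendropy.Node()
        node.edge.length = 1.0
        parent.add_child(node)
        return node

    for rec in records:
        if rec.order == UNKNOWN_TAXON or rec.family == UNKNOWN_TAXON:
            parent = tree.seed_node
        else:
            if rec.order not in order_nodes:
                order_nodes[rec.order] = _child(tree.seed_node)
            okey = rec.order
            fkey = (rec.order, rec.family)
            if fkey not in family_nodes:
                family_nodes[fkey] = _child(order_nodes[okey])
            gkey = (rec.order, rec.family, genus_of(rec.species))
            if gkey not in genus_nodes:
                genus_nodes[gkey] = _child(family_nodes[fkey])
            parent = genus_nodes[gkey]
        leaf = _child(parent)
        leaf.taxon = tns.require_taxon(label=rec.species)
    return tree


def _tip_labels(tree: dendropy.Tree) -> list[str]:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("tip labels must be unique")
    return labels


def phylo_covariance(
    tree: dendropy.Tree, default_length: float = 1.0
) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion tip covariance matrix: shared root-to-MRCA path length.

    ``C[i, j]`` is the summed branch length from the root to the most
    recent common ancestor of tips i and j; the diagonal is the
    root-to-tip distance.  Edges without a stored length get
    ``default_length``.
    """
    labels = _tip_labels(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))

    def elen(node: dendropy.Node) -> float:
        if node.parent_node is None:
            return 0.0
        return default_length if node.edge.length is None else float(node.edge.length)

    depth: dict[dendropy.Node, float] = {}
    tipsets: dict[dendropy.Node, list[int]] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depth[node] = (depth[parent] if parent is not None else 0.0) + elen(node)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            tipsets[node] = [i]
            C[i, i] = depth[node]
        else:
            children = [tipsets[ch] for ch in node.child_nodes()]
            d = depth[node]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            C[i, j] = C[j, i] = d
            tipsets[node] = [i for ch in children for i in ch]
    return C, labels


def _trait_vector(trait: Mapping[str, float], labels: Sequence[str]) -> np.ndarray:
    missing = [lab for lab in labels if lab not in trait]
    if missing:
        raise ValueError(f"missing trait values for tips: {missing[:5]}")
    x = np.asarray([float(trait[lab]) for lab in labels])
    if not np.all(np.isfinite(x)):
        raise ValueError("trait values must be finite")
    return x


def parsimony_steps_continuous(
    tree: dendropy.Tree, trait: Mapping[str, float]
) -> float:
    """Minimum total absolute change of a continuous character on a tree.

    Linear (Farris/Manhattan) parsimony: internal nodes may take any real
    value and the cost of an edge is the absolute difference across it.
    Solved exactly by propagating convex piecewise-linear cost functions
    tipward-to-rootward; after the parent-edge relaxation each subtree's
    cost is characterized by a closed optimal interval, so polytomies are
    handled natively.  Branch lengths are ignored (steps are in trait
    units, as in parsimony programs).
    """
    labels = _tip_labels(tree)
    _trait_vector(trait, labels)  # validates coverage
    total = 0.0
    interval: dict[dendropy.Node, tuple[float, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            x = float(trait[node.taxon.label])
            interval[node] = (x, x)
            continue
        L: list[float] = []  # max-heap (negated) of left breakpoints
        R: list[float] = []  # min-heap of right breakpoints
        for ch in node.child_nodes():
            a, b = interval[ch]
            heapq.heappush(L, -a)
            heapq.heappush(R, b)
            if -L[0] > R[0]:
                hi = -heapq.heappop(L)
                lo = heapq.heappop(R)
                total += hi - lo
                heapq.heappush(L, -lo)
                heapq.heappush(R, hi)
        interval[node] = (-L[0], R[0])
    return total


def ci_ri(tree: dendropy.Tree, trait: Mapping[str, float]) -> tuple[float, float]:
    """Consistency and retention indices of a continuous character.

    ``ci = m / s`` and ``ri = (g - s) / (g - m)`` with s the observed
    parsimony steps, m the trait range (the minimum conceivable steps) and
    g the worst-case steps, taken as the star-tree cost
    ``sum_i |x_i - median(x)|`` — the continuous analogue of the discrete
    worst case.  CI = 1 means no homoplasy; RI near 1 means the tree
    retains the character well.
    """
    labels = _tip_labels(tree)
    x = _trait_vector(trait, labels)
    m = float(np.ptp(x))
    if m == 0:
        raise ValueError("constant trait: consistency index undefined")
    s = parsimony_steps_continuous(tree, trait)
    g = float(np.abs(x - np.median(x)).sum())
    ci = m / s
    ri = (g - s) / (g - m) if g > m else float("nan")
    return ci, ri


def _check_branch_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is None:
            continue
        if edge.length is not None and edge.length <= 0:
            raise ValueError("all branch lengths must be positive for K/lambda")


def _gls_mse(Ci: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Ordinary and phylogenetic mean squared errors about the GLS mean."""
    n = x.size
    one = np.ones(n)
    Ci1 = Ci @ one
    ahat = float(x @ Ci1) / float(one @ Ci1)
    e = x - ahat
    mse0 = float(e @ e) / (n - 1)
    mse = float(e @ Ci @ e) / (n - 1)
    return mse0, mse


def blomberg_k(
    tree: dendropy.Tree,
    trait: Mapping[str, float],
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Blomberg's K with a tip-randomization significance test.

    K is the observed ratio of the ordinary to the phylogenetically
    corrected mean squared error (about the GLS mean), standardized by its
    Brownian-motion expectation on the tree, so K ~ 1 under Brownian
    evolution and K -> 0 with no signal.  The p-value is the proportion of
    tip-shuffled datasets whose phylogenetic MSE is at most the observed
    one (smaller MSE = more signal), with the +1 continuity correction.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _check_branch_lengths(tree)
    C, labels = phylo_covariance(tree)
    n = len(labels)
    if n <= 3:
        raise ValueError(f"need more than 3 tips for Blomberg's K, got {n}")
    x = _trait_vector(trait, labels)
    if np.ptp(x) == 0:
        raise ValueError("constant trait: K undefined")
    Ci = np.linalg.inv(C)
    mse0, mse = _gls_mse(Ci, x)
    expected = (float(np.trace(C)) - n / float(np.ones(n) @ Ci @ np.ones(n))) / (n - 1)
    k = (mse0 / mse) / expected
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        _, mse_p = _gls_mse(Ci, rng.permutation(x))
        if mse_p <= mse:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return float(k), float(p)


def _lambda_loglik(lam: float, C: np.ndarray, x: np.ndarray) -> float:
    """Profile log-likelihood of the lambda model (rate and mean profiled out)."""
    n = x.size
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    try:
        cho = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"singular covariance at lambda={lam:g}: {err}") from err
    one = np.ones(n)
    Vi1 = cho_solve(cho, one)
    ahat = float(x @ Vi1) / float(one @ Vi1)
    e = x - ahat
    sig2 = float(e @ cho_solve(cho, e)) / n
    if sig2 <= 0:
        return -np.inf
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    return -0.5 * (n * np.log(2.0 * np.pi * sig2) + logdet + n)


def pagel_lambda(
    tree: dendropy.Tree, trait: Mapping[str, float]
) -> tuple[float, float, float]:
    """Maximum-likelihood Pagel's lambda with a likelihood-ratio test.

    lambda scales the off-diagonal entries of the Brownian covariance
    (0 = star tree / no signal, 1 = Brownian motion); the Brownian rate
    and root state are profiled out analytically, leaving a bounded
    one-dimensional search on [0, 1].  The p-value refers
    2*(logL(lambda_hat) - logL(0)) to chi-square with 1 df.  Because the
    null sits on the boundary of the parameter space this reference is
    conservative.

    Returns ``(lambda_hat, logL_at_hat, p)``.
    """
    _check_branch_lengths(tree)
    C, labels = phylo_covariance(tree)
    if len(labels) <= 3:
        raise ValueError(f"need more than 3 tips for Pagel's lambda, got {len(labels)}")
    x = _trait_vector(trait, labels)
    if np.ptp(x) == 0:
        raise ValueError("constant trait: lambda undefined")

    res = minimize_scalar(
        lambda lam: -_lambda_loglik(lam, C, x),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(
            f"lambda optimizer failed on bounds [0, 1]: {res.message}"
        )
    candidates = [0.0, float(res.x), 1.0]
    logls = [_lambda_loglik(lam, C, x) for lam in candidates]
    best = int(np.argmax(logls))
    lam_hat, logl_hat = candidates[best], logls[best]
    lrt = max(0.0, 2.0 * (logl_hat - logls[0]))
    p = float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    return float(lam_hat), float(logl_hat), p


@dataclass(frozen=True)
class SignalStatistics:
    """All phylogenetic-structure statistics for one trait."""

    trait: str
    steps: float
    ci: float
    ri: float
    k: float
    k_p: float
    lam: float
    lam_logL: float
    lam_p: float


SIGNAL_TRAITS = ("voc_index", "uv", "blue", "green", "red")


def signal_table(
    tree: dendropy.Tree,
    records: Sequence[SpeciesTraitRecord],
    traits: Sequence[str] = SIGNAL_TRAITS,
    n_perm: int = 1000,
    seed: int | None = None,
) -> list[SignalStatistics]:
    """Phylogenetic signal statistics for each standard trait.

    VOC enters on the log10 (analysis) scale; bands are the printed
    visible-normalized percentages.  K and lambda are invariant to affine
    trait transforms, so the band scaling convention does not affect them.
    """
    values: dict[str, dict[str, float]] = {t: {} for t in traits}
    for rec in records:
        for t in traits:
            if t == "voc_index":
                values[t][rec.species] = rec.voc_index
            else:
                values[t][rec.species] = getattr(rec.bands, t)
    out = []
    for i, t in enumerate(traits):
        trait = values[t]
        steps = parsimony_steps_continuous(tree, trait)
        ci, ri = ci_ri(tree, trait)
        trait_seed = None if seed is None else seed + i
        k, k_p = blomberg_k(tree, trait, n_perm=n_perm, seed=trait_seed)
        lam, logl, lam_p = pagel_lambda(tree, trait)
        out.append(
            SignalStatistics(
                trait=t, steps=steps, ci=ci, ri=ri, k=k, k_p=k_p,
                lam=lam, lam_logL=logl, lam_p=lam_p,
            )
        )
    return out
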