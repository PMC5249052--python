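"""Fixed-tree discrete-location ancestral reconstruction.

A lightweight empirical-Bayes treatment of discrete phylogeography: given a
rooted tree with branch lengths and a location (one of K discrete regions)
for every tip, the location evolves under a symmetric K-state continuous-time
Markov chain with uniform stationary frequencies.  The single rate parameter
is fitted by maximum likelihood (Felsenstein pruning), and marginal posterior
location probabilities at every internal node follow from the up-down
algorithm with a uniform root prior.

Transition probabilities have the closed form
``P(same, t) = 1/K + (1 - 1/K) exp(-K a t)`` where ``a`` is the
per-pair exchange rate, so for K = 2, P(same) = 1/2 + 1/2 exp(-2 a t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import squareform

__all__ = [
    "upgma_tree",
    "read_tree",
    "location_loglik",
    "fit_rate",
    "ancestral_location_posteriors",
    "transition_matrix",
]


def read_tree(path_or_string, schema: str = "newick") -> dendropy.Tree:
    if isinstance(path_or_string, str) and path_or_string.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=path_or_string, schema=schema)
    else:
        tree = dendropy.Tree.get(path=str(path_or_string), schema=schema)
    tree.is_rooted = True
    return tree


def upgma_tree(dist: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Ultrametric rooted tree by average linkage over a distance matrix."""
    D = np.asarray(dist, dtype=float)
    if D.shape[0] < 2:
        raise ValueError("UPGMA requires at least 2 taxa")
    if D.shape[0] != len(labels):
        raise ValueError("labels must match matrix size")
    Z = linkage(squareform(D, checks=False), method="average")
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    nodes: dict[int, tuple[dendropy.Node, float]] = {}
    for i, lab in enumerate(labels):
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(lab)
        nodes[i] = (node, 0.0)
    n = len(labels)
    for k, (a, b, h, _) in enumerate(Z):
        height = h / 2.0  # linkage height is the inter-cluster distance
        parent = dendropy.Node()
        for child_id in (int(a), int(b)):
            child, child_h = nodes[child_id]
            child.edge.length = height - child_h
            parent.add_child(child)
        nodes[n + k] = (parent, height)
    tree.seed_node = nodes[n + len(Z) - 1][0]
    tree.is_rooted = True
    return tree


def transition_matrix(rate: float, t: float, K: int) -> np.ndarray:
    """Symmetric K-state CTMC transition probabilities after time t."""
    e = math.exp(-K * rate * t)
    same = 1.0 / K + (1.0 - 1.0 / K) * e
    diff = 1.0 / K - e / K
    P = np.full((K, K), diff)
    np.fill_diagonal(P, same)
    return P


def _tip_states(tree: dendropy.Tree, tip_locations: dict[str, str]) -> list[str]:
    states = sorted(set(tip_locations.values()))
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label if leaf.taxon else None
        if name not in tip_locations:
            raise KeyError(f"tip {name!r} has no location")
    return states


def _postorder_partials(
    tree: dendropy.Tree, tip_locations: dict[str, str], rate: float, K: int,
    states: list[str],
) -> dict[dendropy.Node, np.ndarray]:
    idx = {s: k for k, s in enumerate(states)}
    partials: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            v = np.zeros(K)
            v[idx[tip_locations[node.taxon.label]]] = 1.0
            partials[node] = v
        else:
            v = np.ones(K)
            for child in node.child_nodes():
                t = child.edge.length or 0.0
                P = transition_matrix(rate, t, K)
                v = v * (P @ partials[child])
            partials[node] = v
    return partials


def location_loglik(
    tree: dendropy.Tree, tip_locations: dict[str, str], rate: float,
    K: int | None = None,
) -> float:
    """Felsenstein-pruning log-likelihood of tip locations, uniform root prior."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    states = _tip_states(tree, tip_locations)
    K = K if K is not None else len(states)
    if K < len(states):
        raise ValueError("K smaller than the number of observed locations")
    states = states + [f"_unobs{i}" for i in range(K - len(states))]
    partials = _postorder_partials(tree, tip_locations, rate, K, states)
    root = partials[tree.seed_node]
    return float(np.log(np.sum(root) / K))


def fit_rate(
    tree: dendropy.Tree, tip_locations: dict[str, str], K: int | None = None,
    bounds: tuple[float, float] = (1e-8, 1e3),
) -> float:
    """Maximum-likelihood CTMC rate via bounded 1-D optimisation (log scale)."""
    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    res = minimize_scalar(
        lambda lr: -location_loglik(tree, tip_locations, math.exp(lr), K),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"rate optimisation failed: {res.message}")
    return float(math.exp(res.x))


def ancestral_location_posteriors(
    tree: dendropy.Tree,
    tip_locations: dict[str, str],
    K: int | None = None,
    rate: float | None = None,
) -> tuple[dict[dendropy.Node, np.ndarray], list[str], float]:
    """Marginal posterior location probabilities for every internal node.

    The rate is fitted by ML unless supplied.  Returns (posteriors, state
    labels, rate); each posterior vector sums to 1.
    """
    states = _tip_states(tree, tip_locations)
    K = K if K is not None else len(states)
    if rate is None:
        rate = fit_rate(tree, tip_locations, K)
    states_full = states + [f"_unobs{i}" for i in range(K - len(states))]
    partials = _postorder_partials(tree, tip_locations, rate, K, states_full)

    # upward (outside) messages
    up: dict[dendropy.Node, np.ndarray] = {tree.seed_node: np.full(K, 1.0 / K)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        for child in node.child_nodes():
            msg = up[node].copy()
            for sib in node.child_nodes():
                if sib is child:
                    continue
                Ps = transition_matrix(rate, sib.edge.length or 0.0, K)
                msg = msg * (Ps @ partials[sib])
            Pc = transition_matrix(rate, child.edge.length or 0.0, K)
            up[child] = Pc.T @ msg

    posteriors: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        v = up[node] * partials[node]
        posteriors[node] = v / v.sum()
    return posteriors, states_full, rate


@dataclass
class LocationPosterior:
    """Posterior location probabilities for named clades (MRCA of tip sets)."""

    table: "object"


def clade_posteriors(
    tree: dendropy.Tree,
    tip_locations: dict[str, str],
    clades: dict[str, list[str]],
    K: int | None = None,
    rate: float | None = None,
):
    """Posterior vectors for the MRCA of each named tip set."""
    import pandas as pd

    post, states, fitted = ancestral_location_posteriors(tree, tip_locations, K, rate)
    rows = {}
    for name, tips in clades.items():
        taxa = [t for t in tree.taxon_namespace if t.label in set(tips)]
        mrca = tree.mrca(taxa=taxa)
        vec = post.get(mrca)
        if vec is None:  # MRCA of a single tip
            vec = np.zeros(len(states))
            vec[states.index(tip_locations[tips[0]])] = 1.0
        rows[name] = vec
    return pd.DataFrame(rows, index=states).T, fitted
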