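"""Naive reference implementation of per-edge query placement.

For validating :class:`ecoplace.placement.PlacementEngine`: instead of
precomputed midpoint partials and closed-form transition operators, this
module physically builds the augmented tree for every candidate edge (an
undirected adjacency graph with the query hanging off a new midpoint
node) and evaluates the likelihood by plain Felsenstein recursion with
explicit 20x20 transition matrices, optimizing the pendant length with
``scipy.optimize.minimize_scalar``.  Orders of magnitude slower; intended
for small instances only.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .placement import PENDANT_BOUNDS, AlignedQuery, Placement
from .refdata import ReferencePackage
from .substitution import N_STATES, transition_matrix


def _augmented_adjacency(package: ReferencePackage, edge_id: int,
                         pendant: float):
    """Adjacency list of the tree with the query attached at the midpoint
    of `edge_id`.  Node keys: tree node ints, 'm' (midpoint), 'q' (query)."""
    tree = package.tree
    adj: dict = {}

    def add(a, b, length):
        adj.setdefault(a, []).append((b, length))
        adj.setdefault(b, []).append((a, length))

    for node in range(tree.n_nodes):
        p = tree.parent[node]
        if p < 0:
            continue
        if node == edge_id:
            half = tree.branch_length[node] / 2.0
            add(p, "m", half)
            add("m", node, half)
        else:
            add(p, node, tree.branch_length[node])
    add("m", "q", pendant)
    return adj


def _likelihood(package: ReferencePackage, adj, query: AlignedQuery) -> float:
    """Log-likelihood over the query's columns, rooted at the midpoint."""
    tree = package.tree
    cols = query.columns
    nq = len(cols)

    tips: dict = {}
    for node, label in tree.leaf_labels.items():
        codes = package.alignment.encoded(label)[cols]
        part = np.zeros((nq, N_STATES))
        part[codes < 0] = 1.0
        ok = codes >= 0
        part[np.nonzero(ok)[0], codes[ok]] = 1.0
        tips[node] = part
    qpart = np.zeros((nq, N_STATES))
    qpart[np.arange(nq), query.residues] = 1.0
    tips["q"] = qpart

    def partial(node, parent):
        children = [(n, t) for n, t in adj[node] if n != parent]
        if not children:
            return tips[node]
        out = np.ones((nq, N_STATES))
        for child, t in children:
            P = transition_matrix(t)
            out = out * (partial(child, node) @ P.T)
        return out

    lik = (partial("m", None) / N_STATES).sum(axis=1)
    if np.any(lik <= 0):
        return -np.inf
    return float(np.log(lik).sum())


def place_query_bruteforce(query: AlignedQuery, package: ReferencePackage,
                           sample_id: str | None = None) -> Placement | None:
    """Exhaustive per-edge placement with scalar pendant optimization."""
    if len(query.columns) == 0:
        return None
    lo, hi = PENDANT_BOUNDS
    results = []
    for edge in range(package.tree.n_edges):
        def neg_ll(v, _edge=edge):
            adj = _augmented_adjacency(package, _edge, v)
            return -_likelihood(package, adj, query)

        opt = minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        results.append((-opt.fun, float(opt.x), edge))
    best_ll = max(r[0] for r in results)
    if not np.isfinite(best_ll):
        return None
    ll, v, edge = min((r for r in results if r[0] >= best_ll - 1e-9),
                      key=lambda r: r[2])
    return Placement(query_id=query.query_id, gene=query.gene, edge_id=edge,
                     pendant_length=v, log_likelihood=ll,
                     clade=package.labeling[edge], sample_id=sample_id)
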