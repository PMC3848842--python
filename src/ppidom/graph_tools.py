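"""Shared graph machinery for the network stages.

Undirected graphs are held as :class:`networkx.Graph`.  This module adds the
pieces the analyses need under exact determinism: degree centrality,
degree-preserving double-edge-swap randomization, degree-proportional random
graphs, Markov clustering (MCL), and connected components.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np

__all__ = [
    "degree_centrality",
    "randomize_preserving_degree",
    "random_graph_degree_proportional",
    "mcl_cluster",
    "connected_components",
    "graph_from_pairs",
]


def graph_from_pairs(pairs, nodes=()) -> nx.Graph:
    """Simple undirected graph from unordered id pairs (self-loops dropped)."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from((a, b) for a, b in pairs if a != b)
    return g


def degree_centrality(g: nx.Graph, node) -> float:
    """Degree of ``node`` divided by (number of nodes - 1)."""
    if g.number_of_nodes() < 2:
        raise ValueError("degree centrality needs at least 2 nodes")
    if node not in g:
        raise KeyError(f"node {node!r} not in graph")
    return g.degree(node) / (g.number_of_nodes() - 1)


def randomize_preserving_degree(
    g: nx.Graph, seed, n_swaps_factor: int = 10
) -> nx.Graph:
    """Degree-preserving randomization by double edge swaps.

    Attempts ``n_swaps_factor * |E|`` swaps; a swap replaces edges (a,b),(c,d)
    with (a,d),(c,b) and is rejected if it would create a self-loop or a
    multi-edge.  The output's degree sequence equals the input's exactly.  On
    graphs too constrained to swap (fewer than 2 edges) the input is returned
    unchanged with a warning.
    """
    if g.number_of_selfloops() if hasattr(g, "number_of_selfloops") else nx.number_of_selfloops(g):
        raise ValueError("degree-preserving randomization requires a simple graph")
    edges = [tuple(e) for e in g.edges()]
    m = len(edges)
    if m < 2:
        warnings.warn("graph too constrained to swap; returning input copy")
        return g.copy()
    rng = np.random.default_rng(seed)
    edge_set = {frozenset(e) for e in edges}
    n_attempts = n_swaps_factor * m
    idx = rng.integers(0, m, size=(n_attempts, 2))
    flips = rng.integers(0, 2, size=n_attempts)
    for t in range(n_attempts):
        i, j = idx[t]
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flips[t]:
            c, d = d, c
        # propose (a,d) and (c,b)
        if a == d or c == b:
            continue
        e1, e2 = frozenset((a, d)), frozenset((c, b))
        if e1 in edge_set or e2 in edge_set or e1 == e2:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = (a, d)
        edges[j] = (c, b)
    out = nx.Graph()
    out.add_nodes_from(g.nodes())
    out.add_edges_from(edges)
    return out


def random_graph_degree_proportional(
    degree_template: dict, n_edges: int, seed, retry_factor: int = 100
) -> nx.Graph:
    """Random simple graph whose endpoints are sampled in proportion to a
    degree template.

    Edges are accepted by sampling two distinct endpoints with probability
    proportional to their template degree, rejecting self-pairs and duplicate
    edges, until ``n_edges`` are placed.  Nodes with template degree 0 are
    never sampled.
    """
    nodes = sorted(degree_template)
    weights = np.array([max(0.0, float(degree_template[n])) for n in nodes])
    total = weights.sum()
    if total <= 0:
        raise ValueError("degree template has no positive weight")
    eligible = [n for n, w in zip(nodes, weights) if w > 0]
    max_edges = len(eligible) * (len(eligible) - 1) // 2
    if n_edges > max_edges:
        raise ValueError(
            f"n_edges={n_edges} infeasible for {len(eligible)} sampleable nodes"
        )
    p = weights / total
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    budget = retry_factor * max(n_edges, 1)
    accepted = 0
    while accepted < n_edges:
        if budget <= 0:
            raise RuntimeError(
                "degree-proportional sampling exhausted its retry budget; "
                "the requested edge count is too dense for the template"
            )
        budget -= 1
        i, j = rng.choice(len(nodes), size=2, p=p)
        if i == j:
            continue
        u, v = nodes[i], nodes[j]
        if g.has_edge(u, v):
            continue
        g.add_edge(u, v)
        accepted += 1
    return g


def mcl_cluster(
    g: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 200,
    tol: float = 1e-6,
    prune: float = 1e-5,
) -> list[set]:
    """Markov clustering of a weighted undirected graph.

    Alternates expansion (matrix power) and inflation (elementwise power then
    column renormalization) on the column-stochastic transition matrix, with
    pruning of tiny entries, until the change between iterations falls below
    ``tol``.  Self-loops are added with weight equal to the node's maximum
    incident weight (1 for isolated nodes) to damp periodicity.  Clusters are
    read from the attractor rows; every node is assigned to exactly one
    cluster (ties broken by lowest attractor index).
    """
    nodes = sorted(g.nodes())
    n = len(nodes)
    if n == 0:
        return []
    index = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise ValueError("MCL requires non-negative edge weights")
        M[index[u], index[v]] = w
        M[index[v], index[u]] = w
    loop = M.max(axis=0)
    loop[loop <= 0] = 1.0
    np.fill_diagonal(M, loop)
    M = M / M.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        last = M
        M = np.linalg.matrix_power(M, expansion)
        M = np.power(M, inflation)
        M[M < prune] = 0.0
        colsums = M.sum(axis=0, keepdims=True)
        # A pruned-out column falls back to staying put.
        dead = np.nonzero(colsums[0] == 0)[0]
        for j in dead:
            M[j, j] = 1.0
        M = M / M.sum(axis=0, keepdims=True)
        if np.abs(M - last).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within max_iter; clustering current state")
    # Attractors: rows with positive diagonal mass.
    attractors = [i for i in range(n) if M[i, i] > tol]
    clusters: list[set] = []
    assigned: dict[int, int] = {}
    for a in attractors:
        members = set(np.nonzero(M[a] > tol)[0].tolist()) | {a}
        merged = None
        for ci in sorted({assigned[m] for m in members if m in assigned}):
            if merged is None:
                merged = ci
            else:  # overlapping attractor systems join the lowest cluster
                clusters[merged] |= clusters[ci]
                clusters[ci] = set()
        if merged is None:
            clusters.append(set())
            merged = len(clusters) - 1
        clusters[merged] |= members
        for m in clusters[merged]:
            assigned[m] = merged
    # Unassigned nodes (no attractor mass) go with their strongest column entry.
    for j in range(n):
        if j not in assigned:
            i = int(np.argmax(M[:, j]))
            target = assigned.get(i)
            if target is None:
                clusters.append({j})
                assigned[j] = len(clusters) - 1
            else:
                clusters[target].add(j)
                assigned[j] = target
    out = [
        {nodes[i] for i in members} for members in clusters if members
    ]
    out.sort(key=lambda s: (-len(s), min(s)))
    return out


def connected_components(g: nx.Graph) -> list[set]:
    """Reachability partition, largest first."""
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda s: (-len(s), min(s)))
    return comps
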