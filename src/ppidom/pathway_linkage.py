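"""Pathway-pathway linkage networks from predicted interactions.

Two metabolic pathways are linked when more predicted interactions join their
member proteins than in at least a ``quantile`` fraction (default 99.9%) of
degree-preserving randomizations of the PPI network.  Retained linkages are
weighted by the fraction of possible non-self inter-pathway pairs realised,
flagged for sharing of non-ubiquitous compounds, clustered with MCL, and the
clusters tested for pathway-class enrichment with an annotation-count
hypergeometric that corrects for the bias of Fisher's exact test toward
heavily annotated branches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import networkx as nx
import numpy as np

from .graph_tools import graph_from_pairs, randomize_preserving_degree
from .io_formats import OntologyDAG, canonical_pair
from .rf_classifier import PredictionSet

__all__ = [
    "PathwaySet",
    "LinkageNetwork",
    "EnrichmentResult",
    "count_interpathway",
    "significant_linkages",
    "compound_sharing_test",
    "enrichment_p",
    "cluster_enrichment",
]


@dataclass
class PathwaySet:
    """pathway id -> (member proteins, compounds, ontology class annotations)."""

    members: dict[str, set]
    compounds: dict[str, set] = field(default_factory=dict)
    classes: dict[str, set] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, prots in self.members.items():
            if not prots:
                raise ValueError(f"pathway {pid!r} has no member proteins")

    def ids(self) -> list[str]:
        return sorted(self.members)

    def ubiquitous_compounds(self, max_pathways: int = 15) -> set:
        """Compounds present in more than ``max_pathways`` pathways (too
        common to signal a meaningful linkage, e.g. ATP)."""
        count: dict[str, int] = {}
        for comps in self.compounds.values():
            for c in comps:
                count[c] = count.get(c, 0) + 1
        return {c for c, n in count.items() if n > max_pathways}


@dataclass
class LinkageNetwork:
    """Weighted pathway-pathway (or disease-disease) graph with the null
    statistics attached per retained edge."""

    graph: nx.Graph
    n_random: int
    quantile: float

    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges())

    def __len__(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class EnrichmentResult:
    cluster: int
    term: str
    M_g: int
    M_gt: int
    M_t: int
    M_tot: int
    p: float
    significant: bool


def _possible_nonself_pairs(a_members: set, b_members: set) -> int:
    """Unordered protein pairs {u, v}, u in A, v in B, u != v."""
    k = len(a_members & b_members)
    return len(a_members) * len(b_members) - k - k * (k - 1) // 2


def _count_from_edges(
    edges, membership: dict[str, list[str]]
) -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    for u, v in edges:
        if u == v:
            continue  # predicted self-interactions never support a linkage
        pu = membership.get(u)
        pv = membership.get(v)
        if not pu or not pv:
            continue
        seen: set[tuple[str, str]] = set()
        for a in pu:
            for b in pv:
                if a == b:
                    continue
                key = canonical_pair(a, b)
                if key not in seen:
                    seen.add(key)
                    counts[key] = counts.get(key, 0) + 1
    return counts


def _membership_index(pathways: PathwaySet) -> tuple[dict[str, list[str]], int]:
    """protein -> sorted pathway ids; also counts member proteins with no
    entry in the prediction network (callers may warn)."""
    membership: dict[str, list[str]] = {}
    for pid in pathways.ids():
        for prot in pathways.members[pid]:
            membership.setdefault(prot, []).append(pid)
    for prot in membership:
        membership[prot].sort()
    return membership, len(membership)


def count_interpathway(
    predictions: PredictionSet, pathways: PathwaySet
) -> dict[tuple[str, str], int]:
    """Count predicted interactions between the member sets of each unordered
    pathway pair, excluding self-interactions; a pathway pair with no cross
    edges is absent from the map."""
    membership, _ = _membership_index(pathways)
    return _count_from_edges(predictions.pairs(), membership)


def significant_linkages(
    predictions: PredictionSet,
    pathways: PathwaySet,
    n_random: int = 10000,
    quantile: float = 0.999,
    seed: int = 0,
    max_pathways_per_compound: int = 15,
) -> LinkageNetwork:
    """Retain pathway pairs whose observed inter-pathway interaction count
    strictly exceeds the count in at least ``quantile * n_random``
    degree-preserving randomizations of the PPI network (ties count against
    retention)."""
    observed = count_interpathway(predictions, pathways)
    membership, _ = _membership_index(pathways)
    ppi = graph_from_pairs(predictions.pairs())
    exceed = {pair: 0 for pair in observed}
    child = np.random.SeedSequence(seed).spawn(n_random)
    for r in range(n_random):
        rg = randomize_preserving_degree(ppi, seed=child[r])
        rcounts = _count_from_edges(rg.edges(), membership)
        for pair, obs in observed.items():
            if obs > rcounts.get(pair, 0):
                exceed[pair] += 1
    need = math.ceil(quantile * n_random)
    ubiq = pathways.ubiquitous_compounds(max_pathways_per_compound)
    g = nx.Graph()
    g.add_nodes_from(pathways.ids())
    for (pa, pb), obs in sorted(observed.items()):
        if exceed[(pa, pb)] < need:
            continue
        possible = _possible_nonself_pairs(
            pathways.members[pa], pathways.members[pb]
        )
        comps_a = pathways.compounds.get(pa, set()) - ubiq
        comps_b = pathways.compounds.get(pb, set()) - ubiq
        g.add_edge(
            pa,
            pb,
            n_interactions=obs,
            n_exceed=exceed[(pa, pb)],
            weight=obs / possible if possible else 0.0,
            shares_compound=bool(comps_a & comps_b),
        )
    return LinkageNetwork(graph=g, n_random=n_random, quantile=quantile)


def compound_sharing_test(
    linkage: LinkageNetwork,
    pathways: PathwaySet,
    max_pathways_per_compound: int = 15,
    n_random: int = 10000,
    seed: int = 0,
) -> tuple[int, float, float, float]:
    """Do linked pathways share compounds more often than expected?

    Counts retained linkages whose two pathways share at least one
    non-ubiquitous compound, against degree-preserving randomizations of the
    linkage graph itself.  Returns (observed, null mean, null sd, empirical p)
    with p floored at 1/(n_random + 1).
    """
    if len(linkage) == 0:
        raise ValueError("empty linkage network")
    ubiq = pathways.ubiquitous_compounds(max_pathways_per_compound)
    comps = {
        pid: pathways.compounds.get(pid, set()) - ubiq for pid in pathways.ids()
    }

    def n_sharing(edges) -> int:
        return sum(1 for a, b in edges if comps.get(a, set()) & comps.get(b, set()))

    observed = n_sharing(linkage.edges())
    child = np.random.SeedSequence(seed).spawn(n_random)
    null = np.empty(n_random)
    for r in range(n_random):
        rg = randomize_preserving_degree(linkage.graph, seed=child[r])
        null[r] = n_sharing(rg.edges())
    p = max(float((null >= observed).mean()), 1.0 / (n_random + 1))
    return observed, float(null.mean()), float(null.std(ddof=1)), p


def enrichment_p(M_gt: int, M_g: int, M_t: int, M_tot: int) -> float:
    """Hypergeometric upper tail over annotation counts.

    p = sum_{i=M_gt}^{min(M_g, M_t)} C(M_t, i) C(M_tot - M_t, M_g - i)
        / C(M_tot, M_g),
    computed with exact integer arithmetic.
    """
    if not (0 <= M_gt <= min(M_g, M_t) and M_g <= M_tot and M_t <= M_tot):
        raise ValueError(
            f"impossible counts M_gt={M_gt}, M_g={M_g}, M_t={M_t}, M_tot={M_tot}"
        )
    denom = math.comb(M_tot, M_g)
    num = sum(
        math.comb(M_t, i) * math.comb(M_tot - M_t, M_g - i)
        for i in range(M_gt, min(M_g, M_t) + 1)
    )
    return float(Fraction(num, denom))


def cluster_enrichment(
    clusters: list[set],
    ontology: OntologyDAG,
    pathway_classes: dict[str, set],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-cluster pathway-class enrichment with Bonferroni control.

    Each pathway annotates every ontology node that is an ancestor of (or
    equal to) one of its classes — one annotation per (pathway, node) pair.
    M_tot is the total number of such annotations; for a cluster and node t,
    M_g is the cluster's total annotation count, M_t the number of pathways
    annotated to t, and M_gt the number of cluster pathways annotated to t.
    A term is significant when p <= alpha / (n_clusters * n_ontology_nodes).
    """
    ann_nodes: dict[str, frozenset] = {}
    for pid, classes in pathway_classes.items():
        nodes: set = set()
        for c in classes:
            if c not in ontology:
                raise KeyError(f"class {c!r} absent from the ontology")
            nodes |= ontology.ancestors(c)
        ann_nodes[pid] = frozenset(nodes)
    M_tot = sum(len(v) for v in ann_nodes.values())
    node_pathways: dict[str, int] = {}
    for pid, nodes in ann_nodes.items():
        for nd in nodes:
            node_pathways[nd] = node_pathways.get(nd, 0) + 1
    n_O = len(ontology)
    n_C = len(clusters)
    cutoff = alpha / (n_C * n_O) if n_C and n_O else alpha
    results: list[EnrichmentResult] = []
    for ci, cluster in enumerate(clusters):
        annotated = [pid for pid in sorted(cluster) if pid in ann_nodes]
        M_g = sum(len(ann_nodes[pid]) for pid in annotated)
        if M_g == 0:
            continue
        per_node: dict[str, int] = {}
        for pid in annotated:
            for nd in ann_nodes[pid]:
                per_node[nd] = per_node.get(nd, 0) + 1
        for nd in sorted(per_node):
            M_gt = per_node[nd]
            M_t = node_pathways[nd]
            p = enrichment_p(M_gt, M_g, M_t, M_tot)
            results.append(
                EnrichmentResult(
                    cluster=ci,
                    term=nd,
                    M_g=M_g,
                    M_gt=M_gt,
                    M_t=M_t,
                    M_tot=M_tot,
                    p=p,
                    significant=p <= cutoff,
                )
            )
    results.sort(key=lambda r: (r.cluster, r.p, r.term))
    return results
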