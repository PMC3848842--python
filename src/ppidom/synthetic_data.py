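"""Synthetic proteomes, interactomes and annotation tables with planted signal.

The generator emulates the statistical structure the classifier and the
downstream network analyses assume: interaction probability is a logistic
function of a hidden domain-pair affinity sum plus a localization-agreement
term, pathway/disease/expression tables carry coherence knobs that make each
downstream null true (knob at 0) or false (knob up), and duplicate-retention
flags are drawn from the same logistic retention model the regression stage
fits.  Everything is deterministic under the mandatory seed, and every table
can be written through the io_formats writers so the whole pipeline is
testable without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .disease_network import DiseaseEntry, DiseaseTable
from .io_formats import (
    DEFAULT_LOCALIZATION_SCHEMA,
    DominTable,
    ExpressionMatrix,
    InteractionSet,
    OntologyDAG,
    ProteinRecord,
    canonical_pair,
)
from .pathway_linkage import PathwaySet
from .rf_classifier import PredictionSet
from .wgd_regression import DuplicationTable

__all__ = [
    "SimConfig",
    "simulate_proteome",
    "simulate_interactions",
    "simulate_domine",
    "simulate_annotations",
    "simulate_pathway_predictions",
    "simulate_disease_data",
    "simulate_retention_covariates",
    "simulate_duplication_flags",
]


@dataclass
class SimConfig:
    """Study conditions for the generator.

    ``domains_per_protein`` is either a fixed int or an inclusive (low, high)
    uniform range.  ``affinity_strength`` scales the hidden domain-pair
    affinity contribution to the interaction logit; ``localization_strength``
    is the logit bonus for co-compartmental pairs; both at 0 give a uniform
    null interactome.  ``wgd_coefficients`` are (intercept, log-DC, DN,
    interaction) for the retention generator, signed as the gene balance
    hypothesis predicts (negative, negative, positive, positive).
    """

    seed: int
    n_proteins: int = 200
    n_domains: int = 40
    domains_per_protein: int | tuple[int, int] = (1, 3)
    n_true_interactions: int = 600
    affinity_strength: float = 1.0
    localization_strength: float = 1.5
    affinity_pair_fraction: float = 0.25
    n_compartments: int = 4
    localization_noise: float = 0.15
    n_pathways: int = 8
    pathway_size: int = 8
    n_compounds: int = 30
    n_diseases: int = 20
    n_samples: int = 30
    wgd_coefficients: tuple[float, float, float, float] = (-2.0, -0.2, 5.0, 0.6)
    misspecified: bool = False

    def __post_init__(self) -> None:
        for name in (
            "n_proteins", "n_domains", "n_true_interactions", "n_compartments",
            "n_pathways", "pathway_size", "n_compounds", "n_diseases", "n_samples",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator stage."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_proteome(
    cfg: SimConfig,
) -> tuple[list[ProteinRecord], dict[str, dict[str, float]], dict[str, int]]:
    """Proteins with domain content and localization vectors.

    Each protein is assigned to one of ``n_compartments`` archetypes; its
    localization vector is the archetype's compartment-probability profile
    plus Gaussian noise on every feature (zero noise makes co-compartmental
    proteins identical).  Returns (records, localization table,
    protein -> compartment index).
    """
    rng_dom, rng_comp, rng_loc = _child_rngs(cfg.seed, 3)[:3]
    ids = [f"P{i:04d}" for i in range(cfg.n_proteins)]
    # Mildly skewed domain popularity, as real domain families are.
    weights = 1.0 / np.arange(1, cfg.n_domains + 1) ** 0.5
    weights /= weights.sum()
    records: list[ProteinRecord] = []
    if isinstance(cfg.domains_per_protein, int):
        k_lo = k_hi = cfg.domains_per_protein
    else:
        k_lo, k_hi = cfg.domains_per_protein
    compartments = rng_comp.integers(0, cfg.n_compartments, size=cfg.n_proteins)
    schema = list(DEFAULT_LOCALIZATION_SCHEMA)
    n_prob = 8  # compartment-probability block of the default schema
    archetypes = np.zeros((cfg.n_compartments, len(schema)))
    for c in range(cfg.n_compartments):
        probs = np.full(n_prob, 0.05)
        probs[c % n_prob] = 1.0
        probs /= probs.sum()
        raw = rng_loc.normal(0.0, 1.0, size=len(schema) - n_prob)
        archetypes[c] = np.concatenate([probs, raw])
    loc_table: dict[str, dict[str, float]] = {}
    compartment_of: dict[str, int] = {}
    for i, pid in enumerate(ids):
        k = int(rng_dom.integers(k_lo, k_hi + 1))
        doms = rng_dom.choice(cfg.n_domains, size=min(k, cfg.n_domains),
                              replace=False, p=weights)
        records.append(
            ProteinRecord(
                protein_id=pid,
                domains=tuple(f"PF{int(d):05d}" for d in sorted(doms)),
            )
        )
        c = int(compartments[i])
        compartment_of[pid] = c
        vec = archetypes[c] + rng_loc.normal(0.0, cfg.localization_noise, size=len(schema))
        loc_table[pid] = {name: float(v) for name, v in zip(schema, vec)}
        records[-1].localization = loc_table[pid]
    return records, loc_table, compartment_of


def _affinity_table(cfg: SimConfig) -> dict[tuple[str, str], float]:
    """Hidden sparse domain-pair affinity matrix (positive values)."""
    rng = _child_rngs(cfg.seed, 4)[3]
    domains = [f"PF{d:05d}" for d in range(cfg.n_domains)]
    table: dict[tuple[str, str], float] = {}
    for i in range(cfg.n_domains):
        for j in range(i, cfg.n_domains):
            if rng.random() < cfg.affinity_pair_fraction:
                table[canonical_pair(domains[i], domains[j])] = float(
                    rng.gamma(shape=2.0, scale=1.0)
                )
    return table


def simulate_interactions(
    proteome: list[ProteinRecord],
    cfg: SimConfig,
    compartment_of: dict[str, int] | None = None,
) -> tuple[InteractionSet, dict[tuple[str, str], float], dict[tuple[str, str], float]]:
    """Sample a true interactome from the planted logistic model.

    The interaction logit for a pair is ``affinity_strength * (sum of hidden
    affinities over the pair's unique cross domain combinations) +
    localization_strength * [same compartment] + intercept``, with the
    intercept calibrated so the expected edge count equals
    ``n_true_interactions``.  In ``misspecified`` mode the domain term is
    replaced by a latent per-protein compatibility invisible to domain
    features.  Returns (interactions, per-pair probability map, affinity table).
    """
    rng = _child_rngs(cfg.seed, 5)[4]
    affinity = _affinity_table(cfg)
    ids = [p.protein_id for p in proteome]
    index = {p.protein_id: p for p in proteome}
    pairs: list[tuple[str, str]] = []
    logits: list[float] = []
    latent = {pid: rng.normal(0.0, 1.0) for pid in ids} if cfg.misspecified else None
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = index[ids[i]], index[ids[j]]
            if cfg.misspecified:
                s = cfg.affinity_strength * max(
                    0.0, 3.0 - abs(latent[ids[i]] - latent[ids[j]]) * 3.0
                )
            else:
                combos = {
                    canonical_pair(d, e) for d in a.domains for e in b.domains
                }
                s = cfg.affinity_strength * sum(
                    affinity.get(c, 0.0) for c in combos
                )
            if compartment_of is not None and cfg.localization_strength:
                if compartment_of[ids[i]] == compartment_of[ids[j]]:
                    s += cfg.localization_strength
            pairs.append(canonical_pair(ids[i], ids[j]))
            logits.append(s)
    logits_arr = np.asarray(logits)
    target = float(cfg.n_true_interactions)

    def expected(intercept: float) -> float:
        return float(expit(logits_arr + intercept).sum()) - target

    lo, hi = -40.0, 40.0
    intercept = brentq(expected, lo, hi)
    probs = expit(logits_arr + intercept)
    draws = rng.random(len(pairs))
    interactions = InteractionSet(source_label="synthetic")
    prob_map: dict[tuple[str, str], float] = {}
    for pair, p, u in zip(pairs, probs, draws):
        prob_map[pair] = float(p)
        if u < p:
            interactions.pairs.add(pair)
    return interactions, prob_map, affinity


def simulate_domine(
    affinity: dict[tuple[str, str], float], cfg: SimConfig, coverage: float = 0.6
) -> DominTable:
    """Domain-pair confidence table covering a fraction of the planted
    affinity pairs (confidence increases with affinity), emulating an
    external catalogue of known/predicted domain-domain interactions."""
    rng = _child_rngs(cfg.seed, 6)[5]
    table = DominTable()
    for (a, b), aff in sorted(affinity.items()):
        if rng.random() < coverage:
            table.add(a, b, float(np.clip(expit(aff - 2.0), 0.01, 0.99)))
    return table


def simulate_pathway_predictions(
    cfg: SimConfig,
    planted_pairs: list[tuple[str, str]] | None = None,
    n_intra_edges_per_pathway: int = 6,
    n_background_cross_edges: int = 20,
    n_planted_cross_edges: int = 14,
    seed: int | None = None,
) -> tuple[PredictionSet, PathwaySet]:
    """A prediction network plus pathway definitions for linkage testing.

    Pathways are disjoint protein blocks.  The background network mimics the
    within-pathway density of real interactomes: most edges fall inside a
    pathway (these never support a linkage but shape the degree-preserving
    null, which redistributes them across pathways) plus a thin layer of
    uniform cross-pathway edges.  For every planted pathway pair,
    ``n_planted_cross_edges`` extra cross edges join the two member sets, so
    linkage significance testing should recover exactly the planted pairs.
    Planted pathway pairs also share one rare compound.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_prot = cfg.n_pathways * cfg.pathway_size
    ids = [f"P{i:04d}" for i in range(n_prot)]
    members = {
        f"PWY{k:03d}": set(ids[k * cfg.pathway_size : (k + 1) * cfg.pathway_size])
        for k in range(cfg.n_pathways)
    }
    compounds: dict[str, set] = {
        pid: {f"CPD{int(c):03d}" for c in rng.choice(cfg.n_compounds, size=3, replace=False)}
        for pid in sorted(members)
    }
    classes = {
        pid: {f"CLS{(k % 4):02d}"} for k, pid in enumerate(sorted(members))
    }
    scores: dict[tuple[str, str], float] = {}
    for k in range(cfg.n_pathways):
        block = sorted(members[f"PWY{k:03d}"])
        placed = 0
        while placed < n_intra_edges_per_pathway:
            u, v = (block[int(x)] for x in rng.integers(0, len(block), size=2))
            key = canonical_pair(u, v)
            if u == v or key in scores:
                continue
            scores[key] = float(0.65 + 0.3 * rng.random())
            placed += 1
    placed = 0
    while placed < n_background_cross_edges:
        i, j = rng.integers(0, n_prot, size=2)
        if i == j or i // cfg.pathway_size == j // cfg.pathway_size:
            continue
        key = canonical_pair(ids[i], ids[j])
        if key in scores:
            continue
        scores[key] = float(0.65 + 0.3 * rng.random())
        placed += 1
    for pa, pb in planted_pairs or []:
        ma, mb = sorted(members[pa]), sorted(members[pb])
        added = 0
        while added < n_planted_cross_edges:
            u = ma[int(rng.integers(0, len(ma)))]
            v = mb[int(rng.integers(0, len(mb)))]
            key = canonical_pair(u, v)
            if u == v or key in scores:
                continue
            scores[key] = float(0.65 + 0.3 * rng.random())
            added += 1
        shared = f"CPDX{pa}_{pb}"
        compounds[pa].add(shared)
        compounds[pb].add(shared)
    predictions = PredictionSet(scores=scores, threshold=0.65)
    return predictions, PathwaySet(members=members, compounds=compounds, classes=classes)


def _simple_ontology(n_branches: int = 4, leaves_per_branch: int = 3) -> OntologyDAG:
    edges = []
    for b in range(n_branches):
        edges.append((f"T{b:02d}", "ROOT"))
        for l in range(leaves_per_branch):
            edges.append((f"T{b:02d}L{l}", f"T{b:02d}"))
    return OntologyDAG.from_edges(edges)


def simulate_annotations(
    proteome: list[ProteinRecord],
    interactions: InteractionSet,
    cfg: SimConfig,
    go_coherence: float = 0.7,
    pathway_coherence: float = 0.7,
    expression_coherence: float = 0.8,
    disease_coherence: float = 0.8,
) -> dict:
    """Annotation tables with planted structure tied to the interactome.

    Coherence knobs at 0 make every downstream null true (annotations,
    expression and disease links independent of the network); knobs up plant
    the alternative (interactors share terms/pathways, co-express, and linked
    diseases share literature).  Returns a dict with keys ``ontology``,
    ``go_annotations``, ``pathways``, ``expression``, ``diseases``,
    ``duplication``.
    """
    rng_go, rng_pwy, rng_expr, rng_dis, rng_dup = _child_rngs(cfg.seed + 17, 5)
    ids = [p.protein_id for p in proteome]
    edges = sorted(p for p in interactions.pairs if p[0] != p[1])

    # --- ontology + per-gene term annotations -----------------------------
    dag = _simple_ontology()
    leaves = sorted(n for n in dag.nodes() if not (dag.descendants(n) - {n}))
    annotations: dict[str, set] = {
        pid: {leaves[int(rng_go.integers(0, len(leaves)))]} for pid in ids
    }
    for a, b in edges:
        if rng_go.random() < go_coherence:
            annotations[b] = set(annotations[a])

    # --- pathways ----------------------------------------------------------
    # Pathway membership follows the network when coherent: grow pathways by
    # breadth-first absorption along true edges; otherwise random blocks.
    g = nx.Graph()
    g.add_nodes_from(ids)
    g.add_edges_from(edges)
    members: dict[str, set] = {}
    unused = set(ids)
    order = sorted(unused)
    rng_pwy.shuffle(order)
    queue = list(order)
    for k in range(cfg.n_pathways):
        pwy = f"PWY{k:03d}"
        chosen: set = set()
        while queue and not chosen:
            seed_prot = queue.pop()
            if seed_prot in unused:
                chosen = {seed_prot}
        if not chosen:
            break
        frontier = [next(iter(chosen))]
        while frontier and len(chosen) < cfg.pathway_size:
            cur = frontier.pop(0)
            for nb in sorted(g.neighbors(cur)):
                if len(chosen) >= cfg.pathway_size:
                    break
                if nb in unused - chosen and rng_pwy.random() < pathway_coherence:
                    chosen.add(nb)
                    frontier.append(nb)
        while len(chosen) < cfg.pathway_size and unused - chosen:
            pool = sorted(unused - chosen)
            chosen.add(pool[int(rng_pwy.integers(0, len(pool)))])
        unused -= chosen
        members[pwy] = chosen
    compounds = {
        pwy: {
            f"CPD{int(c):03d}"
            for c in rng_pwy.choice(cfg.n_compounds, size=3, replace=False)
        }
        for pwy in sorted(members)
    }
    classes = {
        pwy: {f"CLS{(k % 4):02d}"} for k, pwy in enumerate(sorted(members))
    }
    pathways = PathwaySet(members=members, compounds=compounds, classes=classes)

    # --- expression --------------------------------------------------------
    values = rng_expr.normal(0.0, 1.0, size=(len(ids), cfg.n_samples))
    pos = {pid: i for i, pid in enumerate(ids)}
    c = float(np.clip(expression_coherence, 0.0, 1.0))
    if c > 0:
        tied: set = set()
        for a, b in edges:
            ia, ib = pos[a], pos[b]
            if ia in tied and ib in tied:
                continue
            if ia in tied:
                src, dst = ia, ib
            elif ib in tied:
                src, dst = ib, ia
            else:
                src, dst = ia, ib
                tied.add(src)
            values[dst] = np.sqrt(c) * values[src] + np.sqrt(1 - c) * rng_expr.normal(
                0.0, 1.0, size=cfg.n_samples
            )
            tied.add(dst)
    expression = ExpressionMatrix(
        genes=list(ids),
        samples=[f"S{j:03d}" for j in range(cfg.n_samples)],
        values=values,
    )

    # --- diseases ----------------------------------------------------------
    diseases = simulate_disease_data(
        ids, edges, cfg, coherence=disease_coherence, rng=rng_dis
    )

    # --- duplicate retention ----------------------------------------------
    duplication = simulate_duplication_flags(g, cfg, rng=rng_dup)

    return {
        "ontology": dag,
        "go_annotations": annotations,
        "pathways": pathways,
        "expression": expression,
        "diseases": diseases,
        "duplication": duplication,
    }


def simulate_disease_data(
    ids: list[str],
    edges: list[tuple[str, str]],
    cfg: SimConfig,
    coherence: float = 0.8,
    rng: np.random.Generator | None = None,
) -> DiseaseTable:
    """Disease table whose causative genes sit on true edges when coherent.

    With ``coherence`` up, consecutive disease pairs (D0,D1), (D2,D3), ... are
    planted: their causative genes are the endpoints of true interactions and
    their MeSH terms share most of their PMID pool, so network construction
    and literature scoring both see signal.
    """
    rng = rng or np.random.default_rng(cfg.seed + 23)
    entries: dict[str, DiseaseEntry] = {}
    pool = [f"PMID{m:05d}" for m in range(400)]
    edge_cursor = 0
    for d in range(cfg.n_diseases):
        did = f"OMIM{d:03d}"
        planted = coherence > 0 and d % 2 == 0 and edge_cursor < len(edges)
        if planted and d + 1 < cfg.n_diseases:
            a, b = edges[edge_cursor]
            edge_cursor += 1
            genes_a = {a}
            genes_b = {b}
            shared = set(
                rng.choice(pool, size=30, replace=False).tolist()
            )
            own_a = set(rng.choice(pool, size=10, replace=False).tolist())
            own_b = set(rng.choice(pool, size=10, replace=False).tolist())
            n_shared = int(round(30 * coherence))
            shared = set(sorted(shared)[:n_shared])
            p_a = float(10 ** -rng.uniform(2, 4))
            p_b = float(10 ** -rng.uniform(2, 4))
            entries[did] = DiseaseEntry(
                disease_id=did, genes=genes_a, mesh_term=f"MESH{d:03d}",
                p_om=p_a, pmids=frozenset(shared | own_a),
            )
            did2 = f"OMIM{d + 1:03d}"
            entries[did2] = DiseaseEntry(
                disease_id=did2, genes=genes_b, mesh_term=f"MESH{d + 1:03d}",
                p_om=p_b, pmids=frozenset(shared | own_b),
            )
        elif did not in entries:
            genes = set(
                np.asarray(rng.choice(ids, size=min(2, len(ids)), replace=False)).tolist()
            )
            entries[did] = DiseaseEntry(
                disease_id=did,
                genes=genes,
                mesh_term=f"MESH{d:03d}",
                p_om=float(10 ** -rng.uniform(0.5, 3)),
                pmids=frozenset(rng.choice(pool, size=20, replace=False).tolist()),
            )
    return DiseaseTable(entries)


def simulate_retention_covariates(
    n: int,
    coefficients: tuple[float, float, float, float],
    seed: int,
    n_nodes: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (design matrix, response) directly from the retention model.

    Degree centralities come from a heavy-tailed degree distribution on
    ``n_nodes`` nodes; duplicated-neighbor fractions are Beta(2, 2).  The
    response is Bernoulli with logit = b0 + b1 ln(DC) + b2 DN + b3 ln(DC) DN.
    """
    rng = np.random.default_rng(seed)
    degree = np.maximum(1, rng.zipf(1.8, size=n))
    degree = np.minimum(degree, n_nodes - 1)
    dc = degree / (n_nodes - 1)
    dn = rng.beta(2.0, 2.0, size=n)
    ldc = np.log(dc)
    X = np.column_stack([np.ones(n), ldc, dn, ldc * dn])
    b = np.asarray(coefficients, dtype=float)
    p = expit(X @ b)
    y = (rng.random(n) < p).astype(int)
    return X, y


def simulate_duplication_flags(
    g: nx.Graph,
    cfg: SimConfig,
    event: str = "wgd1",
    n_sweeps: int = 30,
    rng: np.random.Generator | None = None,
) -> DuplicationTable:
    """Retention flags over a network from the logistic retention model.

    Because the duplicated-neighbor covariate depends on the flags
    themselves, flags are drawn by Gibbs sweeps: starting from independent
    draws, each connected gene's flag is resampled from the model given its
    neighbors' current flags.  Captures the model's signs (the target of the
    sign-recovery checks) rather than an exact likelihood.
    """
    rng = rng or np.random.default_rng(cfg.seed + 31)
    b0, b1, b2, b3 = cfg.wgd_coefficients
    genes = sorted(n for n in g.nodes() if g.degree(n) >= 1)
    if not genes:
        raise ValueError("network has no connected genes")
    n_nodes = g.number_of_nodes()
    flags = {gene: int(rng.random() < 0.3) for gene in genes}
    ldc = {
        gene: float(np.log(g.degree(gene) / (n_nodes - 1))) for gene in genes
    }
    for _ in range(n_sweeps):
        for gene in genes:
            nbrs = list(g.neighbors(gene))
            dn = sum(flags.get(nb, 0) for nb in nbrs) / len(nbrs)
            logit = b0 + b1 * ldc[gene] + b2 * dn + b3 * ldc[gene] * dn
            flags[gene] = int(rng.random() < expit(logit))
    return DuplicationTable({event: flags})
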