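"""Disease-disease association networks from predicted PPIs.

Two diseases are associated when predicted interactions join their causative
gene sets more often than in degree-preserving randomizations of the PPI
network.  Associations are scored for literature support by combining the
overlap of the PubMed id sets attached to each disease's best MeSH term with
the significance of the disease-term mapping:

    sim(Mx, My) = -( |Px n Py| / min(|Px|, |Py|) ) * ln( max(p_x, p_y) )

and the observed score distribution is compared to degree-proportional random
networks with a one-sided Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph_tools import random_graph_degree_proportional
from .pathway_linkage import LinkageNetwork, PathwaySet, significant_linkages
from .rf_classifier import PredictionSet

__all__ = [
    "DiseaseEntry",
    "DiseaseTable",
    "build_disease_network",
    "literature_similarity",
    "ks_one_sided",
    "random_disease_networks",
]


@dataclass
class DiseaseEntry:
    disease_id: str
    genes: set
    mesh_term: str | None
    p_om: float | None
    pmids: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"disease {self.disease_id!r} has no causative genes")
        if self.p_om is not None and not 0.0 < self.p_om <= 1.0:
            raise ValueError(
                f"disease {self.disease_id!r}: association p {self.p_om} not in (0,1]"
            )


class DiseaseTable:
    """disease id -> causative genes, best MeSH term with its association
    p-value, and the term's PMID set.  Only the single most significant term
    per disease is kept."""

    def __init__(self, entries: dict[str, DiseaseEntry]):
        self.entries = dict(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, disease_id: str) -> DiseaseEntry:
        return self.entries[disease_id]

    def ids(self) -> list[str]:
        return sorted(self.entries)

    def with_terms(self) -> "DiseaseTable":
        """Drop diseases lacking a mapped MeSH term (they cannot be scored)."""
        return DiseaseTable(
            {d: e for d, e in self.entries.items() if e.mesh_term is not None}
        )


def build_disease_network(
    predictions: PredictionSet,
    diseases: DiseaseTable,
    n_random: int = 10000,
    quantile: float = 0.999,
    seed: int = 0,
) -> LinkageNetwork:
    """Associate diseases whose causative gene sets are joined by more
    predicted interactions than >= ``quantile`` of degree-preserving PPI
    randomizations; self-interactions never count.

    Diseases without a mapped term are dropped first.  Reuses the pathway
    linkage machinery over gene sets (without compound/weight semantics).
    """
    usable = diseases.with_terms()
    gene_sets = PathwaySet(
        members={d: set(usable[d].genes) for d in usable.ids()}
    )
    return significant_linkages(
        predictions,
        gene_sets,
        n_random=n_random,
        quantile=quantile,
        seed=seed,
    )


def literature_similarity(d1: DiseaseEntry, d2: DiseaseEntry) -> float:
    """Literature-support score for a disease pair (symmetric, >= 0).

    Zero when the PMID sets are disjoint or when either disease-term mapping
    is maximally insignificant (p = 1).
    """
    for d in (d1, d2):
        if not d.pmids:
            raise ValueError(f"disease {d.disease_id!r} has an empty PMID set")
        if d.p_om is None:
            raise ValueError(f"disease {d.disease_id!r} has no term mapping")
    overlap = len(d1.pmids & d2.pmids) / min(len(d1.pmids), len(d2.pmids))
    return -overlap * math.log(max(d1.p_om, d2.p_om))


def ks_one_sided(
    observed: list[float], reference: list[float]
) -> tuple[float, float]:
    """One-sided two-sample Kolmogorov-Smirnov test.

    Alternative: the observed sample is stochastically larger than the
    reference, i.e. D = sup_x [F_ref(x) - F_obs(x)].  The p-value is the
    standard one-sided asymptotic bound exp(-2 n m D^2 / (n + m)).
    """
    obs = np.sort(np.asarray(observed, dtype=float))
    ref = np.sort(np.asarray(reference, dtype=float))
    if obs.size == 0 or ref.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([obs, ref])
    f_obs = np.searchsorted(obs, grid, side="right") / obs.size
    f_ref = np.searchsorted(ref, grid, side="right") / ref.size
    d = float(max(0.0, np.max(f_ref - f_obs)))
    n, m = obs.size, ref.size
    p = math.exp(-2.0 * n * m * d * d / (n + m))
    return d, min(p, 1.0)


def random_disease_networks(
    observed: LinkageNetwork,
    diseases: DiseaseTable,
    n: int = 250,
    seed: int = 0,
) -> list[list[float]]:
    """Literature-score samples from degree-proportional random networks.

    Each replicate redraws the observed number of edges with endpoints
    sampled in proportion to the observed network's degrees (degree-0
    diseases never appear), then scores every random edge.  Returns one score
    list per replicate.
    """
    if len(observed) == 0:
        raise ValueError("observed network is empty")
    template = {d: int(deg) for d, deg in observed.graph.degree()}
    n_edges = len(observed)
    child = np.random.SeedSequence(seed).spawn(n)
    out: list[list[float]] = []
    for r in range(n):
        rg = random_graph_degree_proportional(template, n_edges, seed=child[r])
        scores = [
            literature_similarity(diseases[a], diseases[b])
            for a, b in sorted(tuple(sorted(e)) for e in rg.edges())
        ]
        out.append(scores)
    return out


def write_diseases(table: DiseaseTable, diseases_path, pmids_path) -> None:
    """Write the disease snapshot as two TSVs: per-disease rows
    (id, comma-joined genes, best term, association p) and term -> PMID
    mapping rows."""
    from .io_formats import write_mapping

    with open(diseases_path, "w", encoding="utf-8") as fh:
        fh.write("#disease_id\tgenes\tmesh_term\tp_om\n")
        for did in table.ids():
            e = table[did]
            fh.write(
                "\t".join(
                    [
                        did,
                        ",".join(sorted(e.genes)),
                        e.mesh_term or "",
                        repr(float(e.p_om)) if e.p_om is not None else "",
                    ]
                )
                + "\n"
            )
    pmid_map = {
        table[did].mesh_term: sorted(table[did].pmids)
        for did in table.ids()
        if table[did].mesh_term
    }
    write_mapping(pmid_map, pmids_path)


def read_diseases(diseases_path, pmids_path) -> DiseaseTable:
    from .io_formats import ParseError, _data_lines, read_mapping

    pmid_map = read_mapping(pmids_path)
    entries: dict[str, DiseaseEntry] = {}
    for lineno, fields in _data_lines(diseases_path):
        if len(fields) < 4:
            raise ParseError(
                f"{diseases_path}:{lineno}: expected disease, genes, term, p"
            )
        did, genes_s, term, p_s = (f.strip() for f in fields[:4])
        term_val = term or None
        entries[did] = DiseaseEntry(
            disease_id=did,
            genes={g for g in genes_s.split(",") if g},
            mesh_term=term_val,
            p_om=float(p_s) if p_s else None,
            pmids=frozenset(pmid_map.get(term_val, set())) if term_val else frozenset(),
        )
    return DiseaseTable(entries)


def network_literature_scores(
    network: LinkageNetwork, diseases: DiseaseTable
) -> list[float]:
    """Literature score for every retained association edge."""
    return [
        literature_similarity(diseases[a], diseases[b]) for a, b in network.edges()
    ]
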