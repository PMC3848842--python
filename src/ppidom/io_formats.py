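"""Readers, writers and core container types for every table the pipeline touches.

All tabular interfaces are UTF-8, TAB-separated text with ``#``-prefixed
comment lines ignored.  Unordered pairs (of proteins, domains, pathways,
diseases) are canonicalised everywhere as lexicographically sorted tuples.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd

__all__ = [
    "ProteinRecord",
    "InteractionSet",
    "DominTable",
    "ExpressionMatrix",
    "OntologyDAG",
    "ParseError",
    "ValidationError",
    "canonical_pair",
    "read_protein_domains",
    "write_protein_domains",
    "read_interactions",
    "write_interactions",
    "read_localization",
    "write_localization",
    "read_domine",
    "write_domine",
    "read_expression",
    "write_expression",
    "read_ontology",
    "DEFAULT_LOCALIZATION_SCHEMA",
]

#: Default localization feature schema: per-compartment probabilities from a
#: high-resolution subcellular localization predictor plus one raw score per
#: subprogram.  Any consistent named numeric vector is accepted; this list is
#: only the default used by the synthetic generator.
DEFAULT_LOCALIZATION_SCHEMA: tuple[str, ...] = (
    "cytoplasm",
    "nucleus",
    "peroxisome",
    "ER",
    "mitochondria",
    "chloroplast",
    "vacuole",
    "lysosome",
    "SVMTarget",
    "SVMSA",
    "SVMaac",
    "PhyloLoc",
    "GOLoc",
    "MotifSearch",
)


class ParseError(ValueError):
    """Raised when an input file is syntactically malformed."""


class ValidationError(ValueError):
    """Raised when an input file parses but violates a semantic invariant."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered-pair key: lexicographically sorted id tuple."""
    return (a, b) if a <= b else (b, a)


@dataclass
class ProteinRecord:
    """One protein: its id, unique PFAM-style domain accessions, and an
    optional named localization feature vector."""

    protein_id: str
    domains: tuple[str, ...] = ()
    localization: dict[str, float] | None = None


@dataclass
class InteractionSet:
    """A set of unordered protein-id pairs (e.g. experimentally verified
    physical interactions).  Self-pairs are permitted on input and flagged."""

    pairs: set[tuple[str, str]] = field(default_factory=set)
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.pairs

    def add(self, a: str, b: str) -> None:
        self.pairs.add(canonical_pair(a, b))

    @property
    def self_pairs(self) -> set[tuple[str, str]]:
        return {p for p in self.pairs if p[0] == p[1]}

    def without_self_pairs(self) -> "InteractionSet":
        return InteractionSet(
            pairs={p for p in self.pairs if p[0] != p[1]},
            source_label=self.source_label,
        )

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.pairs:
            out.add(a)
            out.add(b)
        return out

    def validate_against(self, proteome: Iterable[ProteinRecord]) -> None:
        known = {p.protein_id for p in proteome}
        missing = self.proteins() - known
        if missing:
            raise ValidationError(
                f"{len(missing)} interaction protein id(s) absent from the "
                f"proteome, e.g. {sorted(missing)[:5]}"
            )


class DominTable:
    """Symmetric lookup of domain-pair interaction confidences in [0, 1].

    Repeated entries for the same unordered pair keep the maximum
    confidence (conservative toward "interaction evidence exists").
    """

    def __init__(self, entries: Mapping[tuple[str, str], float] | None = None):
        self._entries: dict[tuple[str, str], float] = {}
        if entries:
            for (a, b), conf in entries.items():
                self.add(a, b, conf)

    def add(self, a: str, b: str, confidence: float) -> None:
        if not 0.0 <= confidence <= 1.0:
            raise ValidationError(
                f"DOMINE confidence {confidence!r} for ({a},{b}) outside [0,1]"
            )
        key = canonical_pair(a, b)
        prev = self._entries.get(key)
        if prev is None or confidence > prev:
            self._entries[key] = confidence

    def lookup(self, a: str, b: str) -> float | None:
        return self._entries.get(canonical_pair(a, b))

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()


@dataclass
class ExpressionMatrix:
    """genes x samples real matrix carrier for co-expression evaluation."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicated gene ids in expression matrix")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        self._index = {g: i for i, g in enumerate(self.genes)}

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def profile(self, gene: str) -> np.ndarray:
        return self.values[self._index[gene]]

    @property
    def n_samples(self) -> int:
        return len(self.samples)


class OntologyDAG:
    """Rooted directed acyclic graph of ontology terms with is-a edges.

    Edges point child -> parent (the OBO convention).  Serves both the
    GO-style semantic-similarity computation and pathway-class enrichment.
    """

    def __init__(self, graph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            raise ValidationError("ontology graph contains a cycle")
        self._g = graph
        # Caches: ancestor/descendant closures are queried heavily.
        self._anc: dict[str, frozenset[str]] = {}
        self._desc: dict[str, frozenset[str]] = {}

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()
    ) -> "OntologyDAG":
        """Build from (child, parent) pairs plus optional isolated nodes."""
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        return cls(g)

    @property
    def graph(self) -> nx.DiGraph:
        return self._g

    def __contains__(self, term: str) -> bool:
        return term in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    def roots(self) -> set[str]:
        return {n for n in self._g.nodes if self._g.out_degree(n) == 0}

    def ancestors(self, term: str) -> frozenset[str]:
        """Terms reachable upward from ``term``, *including* the term itself."""
        if term not in self._anc:
            self._anc[term] = frozenset(nx.descendants(self._g, term)) | {term}
        return self._anc[term]

    def descendants(self, term: str) -> frozenset[str]:
        """Terms below ``term``, *including* the term itself."""
        if term not in self._desc:
            self._desc[term] = frozenset(nx.ancestors(self._g, term)) | {term}
        return self._desc[term]


# ---------------------------------------------------------------------------
# Line-oriented TSV helpers


def _data_lines(path) -> Iterable[tuple[int, list[str]]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_protein_domains(path) -> list[ProteinRecord]:
    """Read a tab-delimited list of proteins and their constituent domains.

    Each line is ``protein_id<TAB>domain<TAB>domain...``; a line with only an
    id is a domain-less protein.  Duplicated domains within one protein are
    collapsed (only unique domains per protein are kept), preserving first-seen
    order.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for lineno, fields in _data_lines(path):
        pid = fields[0].strip()
        if not pid:
            raise ParseError(f"{path}:{lineno}: empty protein id")
        if pid in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate protein id {pid!r}")
        seen.add(pid)
        domains: list[str] = []
        for d in fields[1:]:
            d = d.strip()
            if not d:
                raise ParseError(f"{path}:{lineno}: empty domain field")
            if d not in domains:
                domains.append(d)
        records.append(ProteinRecord(protein_id=pid, domains=tuple(domains)))
    return records


def write_protein_domains(records: Sequence[ProteinRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write("\t".join((rec.protein_id, *rec.domains)) + "\n")


def read_interactions(path, dedupe: bool = True, source_label: str = "") -> InteractionSet:
    """Read two-column interaction pairs; (A,B) and (B,A) collapse when
    ``dedupe`` (they always share one canonical key; dedupe=False raises on
    a literal repeat instead of silently collapsing)."""
    out = InteractionSet(source_label=source_label or str(path))
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected two tab-separated ids")
        a, b = fields[0].strip(), fields[1].strip()
        if not a or not b:
            raise ParseError(f"{path}:{lineno}: empty protein id")
        key = canonical_pair(a, b)
        if not dedupe and key in out.pairs:
            raise ValidationError(f"{path}:{lineno}: duplicate pair {key}")
        out.pairs.add(key)
    return out


def write_interactions(interactions: InteractionSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(interactions.pairs):
            fh.write(f"{a}\t{b}\n")


def read_localization(path) -> dict[str, dict[str, float]]:
    """Read a header-labelled localization feature table.

    The header row names the features (first column is the protein id); every
    row must match the header's arity and parse as reals.  Compartment
    probabilities are *not* renormalised — raw subprogram scores are
    unnormalised by nature.
    """
    lines = list(_data_lines(path))
    if not lines:
        raise ParseError(f"{path}: empty localization table")
    header_lineno, header = lines[0]
    names = [h.strip() for h in header[1:]]
    if not names:
        raise ParseError(f"{path}:{header_lineno}: header names no features")
    out: dict[str, dict[str, float]] = {}
    for lineno, fields in lines[1:]:
        if len(fields) != len(names) + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {len(names) + 1} columns, got {len(fields)}"
            )
        pid = fields[0].strip()
        if pid in out:
            raise ValidationError(f"{path}:{lineno}: duplicate protein id {pid!r}")
        try:
            vec = {n: float(v) for n, v in zip(names, fields[1:])}
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric feature value ({exc})")
        out[pid] = vec
    return out


def write_localization(loc: Mapping[str, Mapping[str, float]], path) -> None:
    if not loc:
        raise ValidationError("refusing to write empty localization table")
    names = list(next(iter(loc.values())).keys())
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["id", *names]) + "\n")
        for pid in sorted(loc):
            vec = loc[pid]
            if set(vec) != set(names):
                raise ValidationError(
                    f"protein {pid!r} has a different localization schema"
                )
            fh.write("\t".join([pid, *(repr(float(vec[n])) for n in names)]) + "\n")


def read_domine(path) -> DominTable:
    """Read ``domain TAB domain TAB confidence`` lines into a symmetric table;
    repeated pairs keep the maximum confidence."""
    table = DominTable()
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected domain, domain, confidence")
        try:
            conf = float(fields[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric confidence {fields[2]!r}")
        try:
            table.add(fields[0].strip(), fields[1].strip(), conf)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}")
    return table


def write_domine(table: DominTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (a, b), conf in sorted(table.items()):
            fh.write(f"{a}\t{b}\t{repr(float(conf))}\n")


def read_expression(path) -> ExpressionMatrix:
    """Read a gene x sample TSV (header = sample ids, first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.values, index=expr.genes, columns=expr.samples)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_mapping(path) -> dict[str, set[str]]:
    """Generic two-column multi-map (``key TAB value`` per line), e.g.
    pathway -> member proteins, pathway -> compounds, term -> PMIDs."""
    out: dict[str, set[str]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected two tab-separated columns")
        key, value = fields[0].strip(), fields[1].strip()
        if not key or not value:
            raise ParseError(f"{path}:{lineno}: empty field")
        out.setdefault(key, set()).add(value)
    return out


def write_mapping(mapping: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(mapping):
            for value in sorted(mapping[key]):
                fh.write(f"{key}\t{value}\n")


def read_ontology(path) -> tuple[OntologyDAG, dict[str, str]]:
    """Read an OBO file (id / name / is_a stanzas) into an OntologyDAG.

    Returns the DAG plus an id -> name map.  Uses obonet; obsolete terms are
    already dropped by the parser.
    """
    g = obonet.read_obo(path)
    dag = nx.DiGraph()
    dag.add_nodes_from(g.nodes)
    for child, parent, key in g.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent)
    names = {n: data.get("name", n) for n, data in g.nodes(data=True)}
    return OntologyDAG(dag), names


def write_ontology(
    edges: Iterable[tuple[str, str]], path, names: Mapping[str, str] | None = None
) -> None:
    """Write (child, parent) is-a edges as a minimal OBO file."""
    names = dict(names or {})
    children: dict[str, list[str]] = {}
    nodes: set[str] = set()
    for child, parent in edges:
        children.setdefault(child, []).append(parent)
        nodes.add(child)
        nodes.add(parent)
    buf = io.StringIO()
    buf.write("format-version: 1.2\n")
    for node in sorted(nodes):
        buf.write(f"\n[Term]\nid: {node}\nname: {names.get(node, node)}\n")
        for parent in sorted(children.get(node, [])):
            buf.write(f"is_a: {parent}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
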