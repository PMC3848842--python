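"""Classifier performance and functional-plausibility measures.

Beyond sensitivity/specificity and ROC AUC on held-out pairs, predicted
networks are assessed for biological plausibility: do predicted interactors
share metabolic-pathway annotations (Jaccard), have semantically similar GO
annotations (information content of the least-probable shared ancestor), and
show correlated expression profiles more often than degree-matched random
networks?
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .graph_tools import graph_from_pairs, randomize_preserving_degree
from .io_formats import ExpressionMatrix, OntologyDAG

__all__ = [
    "ConfusionCounts",
    "SimilarityResult",
    "confusion",
    "sensitivity",
    "specificity",
    "roc_auc",
    "kegg_similarity",
    "go_term_probability",
    "go_similarity",
    "protein_go_similarity",
    "coexpression_enrichment",
    "functional_similarity_null",
]


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class SimilarityResult:
    observed: float
    null_samples: list[float] = field(default_factory=list)
    n_random: int = 0
    bootstrap_ci: tuple[float, float] | None = None

    @property
    def null_range(self) -> tuple[float, float] | None:
        if not self.null_samples:
            return None
        return (min(self.null_samples), max(self.null_samples))

    def null_ci(self, level: float = 0.95) -> tuple[float, float] | None:
        if not self.null_samples:
            return None
        lo = (1 - level) / 2 * 100
        return tuple(np.percentile(self.null_samples, [lo, 100 - lo]))

    @property
    def exceeds_null_range(self) -> bool | None:
        rng = self.null_range
        if rng is None:
            return None
        return self.observed > rng[1]


def confusion(predicted_pairs: set, truth_pos: set, truth_neg: set) -> ConfusionCounts:
    """Counts against disjoint positive/negative truth pair sets."""
    if truth_pos & truth_neg:
        raise ValueError("truth sets must be disjoint")
    tp = len(predicted_pairs & truth_pos)
    fp = len(predicted_pairs & truth_neg)
    return ConfusionCounts(
        TP=tp,
        FP=fp,
        TN=len(truth_neg) - fp,
        FN=len(truth_pos) - tp,
    )


def sensitivity(c: ConfusionCounts) -> float | None:
    """TP / (TP + FN); None when undefined (no positives)."""
    denom = c.TP + c.FN
    return c.TP / denom if denom else None


def specificity(c: ConfusionCounts) -> float | None:
    """TN / (TN + FP); None when undefined (no negatives)."""
    denom = c.TN + c.FP
    return c.TN / denom if denom else None


def roc_auc(scored: list[tuple[float, int]]) -> float:
    """Area under the ROC curve via the Mann-Whitney identity.

    Equals the probability that a uniformly random positive outscores a
    uniformly random negative, with ties counting one half.
    """
    scores = np.array([s for s, _ in scored], dtype=float)
    labels = np.array([l for _, l in scored], dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both positive and negative examples")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def kegg_similarity(a_annotations: set, b_annotations: set) -> float:
    """Jaccard index of two pathway-annotation sets."""
    if not a_annotations or not b_annotations:
        raise ValueError(
            "pathway similarity is only defined for annotated proteins; "
            "restrict the network before scoring"
        )
    inter = len(a_annotations & b_annotations)
    union = len(a_annotations | b_annotations)
    return inter / union


def go_term_probability(
    dag: OntologyDAG, annotations: dict[str, set]
) -> dict[str, float]:
    """Per-term annotation probability p(c).

    p(c) = (number of annotation occurrences to c or any of its descendants)
    divided by the total number of annotation occurrences.  Each (gene, term)
    annotation counts once; a gene annotated to a term implicitly supports all
    of that term's ancestors.
    """
    direct: dict[str, int] = {t: 0 for t in dag.nodes()}
    total = 0
    for gene, terms in annotations.items():
        for t in terms:
            if t not in dag.graph:
                raise KeyError(f"annotation term {t!r} absent from the ontology")
            direct[t] += 1
            total += 1
    if total == 0:
        raise ValueError("no annotations supplied")
    probs: dict[str, float] = {}
    for c in dag.nodes():
        n_cd = sum(direct[d] for d in dag.descendants(c))
        probs[c] = n_cd / total
    return probs


def go_similarity(cx: str, cy: str, dag: OntologyDAG, probs: dict[str, float]) -> float:
    """-ln of the minimal probability over shared ancestors of the two terms
    (a term is its own ancestor)."""
    shared = dag.ancestors(cx) & dag.ancestors(cy)
    if not shared:
        raise ValueError(
            f"terms {cx!r} and {cy!r} share no ancestor (DAG lacks a common root)"
        )
    usable = [probs[c] for c in shared if probs.get(c, 0.0) > 0.0]
    if not usable:
        warnings.warn(
            f"all shared ancestors of {cx!r}/{cy!r} have zero annotation "
            "probability; similarity undefined"
        )
        return float("nan")
    return -math.log(min(usable))


def protein_go_similarity(
    a_terms: set, b_terms: set, dag: OntologyDAG, probs: dict[str, float]
) -> float:
    """Max over all term cross pairs of the term-term similarity."""
    if not a_terms or not b_terms:
        raise ValueError("both proteins must carry at least one term")
    best = float("-inf")
    for cx in a_terms:
        for cy in b_terms:
            s = go_similarity(cx, cy, dag, probs)
            if not math.isnan(s) and s > best:
                best = s
    return best if best > float("-inf") else float("nan")


def _edge_correlations(
    edges: list[tuple[str, str]], expr: ExpressionMatrix
) -> np.ndarray:
    """Pearson correlation per edge over complete observations; edges with a
    gene absent from the matrix are dropped from the denominator."""
    rho = []
    for a, b in edges:
        if a == b or a not in expr or b not in expr:
            continue
        x, y = expr.profile(a), expr.profile(b)
        mask = np.isfinite(x) & np.isfinite(y)
        if mask.sum() < 3:
            continue
        xm, ym = x[mask], y[mask]
        sx, sy = xm.std(), ym.std()
        if sx == 0 or sy == 0:
            continue
        rho.append(float(np.corrcoef(xm, ym)[0, 1]))
    return np.array(rho)


def coexpression_enrichment(
    edges: list[tuple[str, str]],
    expr: ExpressionMatrix,
    rho_cut: float = 0.5,
    n_boot: int = 250,
    n_random: int = 250,
    seed: int = 0,
) -> SimilarityResult:
    """Fraction of network edges joining co-expressed genes (rho > rho_cut).

    Bootstrap CI resamples edges with replacement; the null CI comes from
    degree-preserving randomizations of the network restricted to measured
    genes.  Self-edges are excluded.
    """
    if expr.n_samples < 3:
        raise ValueError("co-expression needs at least 3 samples")
    edges = sorted({tuple(sorted(e)) for e in edges if e[0] != e[1]})
    rho = _edge_correlations(edges, expr)
    if rho.size == 0:
        raise ValueError("no measurable edges in the expression matrix")
    observed = float((rho > rho_cut).mean())
    ss = np.random.SeedSequence(seed).spawn(2)
    boot_ci = None
    if n_boot > 0:
        rng = np.random.default_rng(ss[0])
        stats = [
            float((rho[rng.integers(0, rho.size, size=rho.size)] > rho_cut).mean())
            for _ in range(n_boot)
        ]
        boot_ci = tuple(np.percentile(stats, [2.5, 97.5]))
    null_samples: list[float] = []
    if n_random > 0:
        g = graph_from_pairs(e for e in edges if e[0] in expr and e[1] in expr)
        child = np.random.SeedSequence(seed).spawn(2)[1].spawn(n_random)
        for r in range(n_random):
            rg = randomize_preserving_degree(g, seed=child[r])
            r_rho = _edge_correlations(sorted(rg.edges()), expr)
            null_samples.append(
                float((r_rho > rho_cut).mean()) if r_rho.size else 0.0
            )
    return SimilarityResult(
        observed=observed,
        null_samples=null_samples,
        n_random=n_random,
        bootstrap_ci=boot_ci,
    )


def functional_similarity_null(
    edges: list[tuple[str, str]],
    annotations: dict[str, set],
    measure: str = "kegg",
    n_random: int = 100,
    seed: int = 0,
    dag: OntologyDAG | None = None,
    kegg_statistic: str = "share_frequency",
) -> SimilarityResult:
    """Observed functional similarity of a network vs degree-preserving nulls.

    The network is first restricted to annotated proteins and self-edges are
    dropped (self-interactions bias similarity upward).  ``measure`` is
    ``"kegg"`` (fraction of edges sharing >= 1 pathway by default, or mean
    Jaccard with ``kegg_statistic="mean_jaccard"``) or ``"go"`` (mean
    protein-level semantic similarity; requires ``dag``).
    """
    annotated = {g for g, terms in annotations.items() if terms}
    kept = sorted(
        {
            tuple(sorted(e))
            for e in edges
            if e[0] != e[1] and e[0] in annotated and e[1] in annotated
        }
    )
    if not kept:
        raise ValueError("annotation restriction emptied the network")
    if measure == "go":
        if dag is None:
            raise ValueError("GO similarity requires the ontology DAG")
        probs = go_term_probability(dag, annotations)

        def stat(edge_list) -> float:
            vals = [
                protein_go_similarity(annotations[a], annotations[b], dag, probs)
                for a, b in edge_list
            ]
            vals = [v for v in vals if not math.isnan(v)]
            return float(np.mean(vals)) if vals else 0.0

    elif measure == "kegg":

        def stat(edge_list) -> float:
            js = [kegg_similarity(annotations[a], annotations[b]) for a, b in edge_list]
            if kegg_statistic == "mean_jaccard":
                return float(np.mean(js))
            return float(np.mean([j > 0 for j in js]))

    else:
        raise ValueError(f"unknown measure {measure!r}")
    observed = stat(kept)
    if n_random < 10:
        warnings.warn(f"n_random={n_random} gives a low-power null range")
    g = graph_from_pairs(kept)
    null_samples: list[float] = []
    child = np.random.SeedSequence(seed).spawn(n_random)
    for r in range(n_random):
        rg = randomize_preserving_degree(g, seed=child[r])
        null_samples.append(stat(sorted(tuple(sorted(e)) for e in rg.edges())))
    return SimilarityResult(
        observed=observed, null_samples=null_samples, n_random=n_random
    )
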