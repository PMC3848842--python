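"""Performance metrics and functional-plausibility measures vs oracles."""

import math

import numpy as np
import pytest

from ppidom.evaluation import (
    ConfusionCounts,
    coexpression_enrichment,
    confusion,
    functional_similarity_null,
    go_similarity,
    go_term_probability,
    kegg_similarity,
    protein_go_similarity,
    roc_auc,
    sensitivity,
    specificity,
)
from ppidom.io_formats import ExpressionMatrix, OntologyDAG


class TestConfusion:
    def test_direct_formulas(self):
        c = ConfusionCounts(TP=3, FP=0, TN=0, FN=1)
        assert sensitivity(c) == 0.75
        c2 = ConfusionCounts(TP=0, FP=5, TN=0, FN=0)
        assert specificity(c2) == 0.0

    def test_perfect_classifier(self):
        pos = {("a", "b"), ("c", "d")}
        neg = {("e", "f")}
        c = confusion(pos, pos, neg)
        assert sensitivity(c) == 1.0 and specificity(c) == 1.0

    def test_zero_denominator_flagged_not_nan(self):
        c = ConfusionCounts(TP=0, FP=0, TN=0, FN=0)
        assert sensitivity(c) is None and specificity(c) is None

    def test_overlapping_truth_rejected(self):
        with pytest.raises(ValueError):
            confusion(set(), {("a", "b")}, {("a", "b")})

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, FP=0, TN=0, FN=0)


def auc_brute_force(scored):
    """O(n^2) pairwise-comparison oracle with half-credit ties."""
    pos = [s for s, l in scored if l == 1]
    neg = [s for s, l in scored if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        scored = [(0.9, 1)] * 5 + [(0.1, 0)] * 5
        assert roc_auc(scored) == 1.0

    def test_all_ties_half(self):
        scored = [(0.5, 1)] * 4 + [(0.5, 0)] * 6
        assert roc_auc(scored) == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        scored = [
            (float(rng.choice([0.1, 0.3, 0.5, 0.7, rng.random()])), int(rng.integers(0, 2)))
            for _ in range(n)
        ]
        labels = {l for _, l in scored}
        if labels != {0, 1}:
            scored += [(0.2, 0), (0.8, 1)]
        assert roc_auc(scored) == pytest.approx(auc_brute_force(scored), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scored = [(float(rng.random()), int(rng.integers(0, 2))) for _ in range(50)]
        scored += [(0.2, 0), (0.8, 1)]
        transformed = [(math.exp(3 * s), l) for s, l in scored]
        assert roc_auc(scored) == pytest.approx(roc_auc(transformed), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([(0.5, 1), (0.6, 1)])


class TestKeggSimilarity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"K1", "K2"}, {"K2", "K3"}, 1 / 3),
            ({"K1"}, {"K1"}, 1.0),
            ({"K1"}, {"K2"}, 0.0),
        ],
    )
    def test_jaccard(self, a, b, expected):
        assert kegg_similarity(a, b) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            kegg_similarity(set(), {"K1"})

    def test_unit_interval_and_identity(self):
        rng = np.random.default_rng(0)
        pool = [f"K{i}" for i in range(6)]
        for _ in range(50):
            a = set(rng.choice(pool, size=rng.integers(1, 5), replace=False))
            b = set(rng.choice(pool, size=rng.integers(1, 5), replace=False))
            j = kegg_similarity(a, b)
            assert 0.0 <= j <= 1.0
            assert (j == 1.0) == (a == b)


def random_dag(rng, n_terms):
    """Random rooted DAG: nodes 1..n each attach upward to >=1 earlier node."""
    edges = []
    for i in range(1, n_terms):
        n_parents = int(rng.integers(1, min(i, 3) + 1))
        parents = rng.choice(i, size=n_parents, replace=False)
        edges.extend((f"t{i}", f"t{int(p)}") for p in parents)
    return OntologyDAG.from_edges(edges, nodes=[f"t{k}" for k in range(n_terms)])


def brute_force_ancestors(dag, term):
    out = {term}
    frontier = [term]
    while frontier:
        cur = frontier.pop()
        for parent in dag.graph.successors(cur):
            if parent not in out:
                out.add(parent)
                frontier.append(parent)
    return out


def brute_force_probs(dag, annotations):
    total = sum(len(v) for v in annotations.values())
    probs = {}
    for c in dag.nodes():
        n = 0
        for terms in annotations.values():
            for t in terms:
                if c in brute_force_ancestors(dag, t):
                    n += 1
        probs[c] = n / total
    return probs


class TestGoSimilarity:
    def test_chain_probabilities(self):
        dag = OntologyDAG.from_edges([("c", "root")])
        probs = go_term_probability(dag, {"g1": {"c"}, "g2": {"root"}})
        assert probs["root"] == 1.0 and probs["c"] == 0.5

    def test_unannotated_subtree_zero(self):
        dag = OntologyDAG.from_edges([("c", "root"), ("d", "root")])
        probs = go_term_probability(dag, {"g1": {"c"}})
        assert probs["d"] == 0.0

    def test_leaf_annotation_propagates_to_ancestors(self):
        dag = OntologyDAG.from_edges([("leaf", "mid"), ("mid", "root")])
        probs = go_term_probability(dag, {"g1": {"leaf"}})
        assert probs["mid"] == 1.0 and probs["root"] == 1.0

    def test_self_similarity_is_neg_log_p(self):
        dag = OntologyDAG.from_edges([("c", "root")])
        probs = go_term_probability(dag, {"g1": {"c"}, "g2": {"root"}})
        assert go_similarity("c", "c", dag, probs) == pytest.approx(
            -math.log(0.5), abs=1e-12
        )

    def test_root_only_sharing_scores_zero(self):
        dag = OntologyDAG.from_edges([("a", "root"), ("b", "root")])
        probs = go_term_probability(dag, {"g1": {"a"}, "g2": {"b"}})
        assert go_similarity("a", "b", dag, probs) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        n_terms = int(rng.integers(4, 31))
        dag = random_dag(rng, n_terms)
        terms = dag.nodes()
        genes = {
            f"g{k}": {terms[int(i)] for i in rng.integers(0, n_terms, size=rng.integers(1, 4))}
            for k in range(int(rng.integers(2, 8)))
        }
        probs = go_term_probability(dag, genes)
        oracle_probs = brute_force_probs(dag, genes)
        for c in terms:
            assert probs[c] == pytest.approx(oracle_probs[c], abs=1e-12)
        for _ in range(10):
            cx, cy = (terms[int(i)] for i in rng.integers(0, n_terms, size=2))
            shared = brute_force_ancestors(dag, cx) & brute_force_ancestors(dag, cy)
            usable = [oracle_probs[c] for c in shared if oracle_probs[c] > 0]
            if not usable:
                continue
            expected = -math.log(min(usable))
            assert go_similarity(cx, cy, dag, probs) == pytest.approx(
                expected, abs=1e-12
            )

    def test_protein_level_max_over_term_pairs(self):
        dag = OntologyDAG.from_edges([("a", "root"), ("b", "root"), ("c", "a")])
        probs = go_term_probability(dag, {"g1": {"c"}, "g2": {"b"}, "g3": {"a"}})
        got = protein_go_similarity({"c", "b"}, {"a"}, dag, probs)
        expected = max(
            go_similarity("c", "a", dag, probs), go_similarity("b", "a", dag, probs)
        )
        assert got == expected

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(99)
        dag = random_dag(rng, 15)
        terms = dag.nodes()
        genes = {f"g{k}": {terms[k % len(terms)]} for k in range(10)}
        probs = go_term_probability(dag, genes)
        for _ in range(20):
            cx, cy = (terms[int(i)] for i in rng.integers(0, len(terms), size=2))
            s = go_similarity(cx, cy, dag, probs)
            if math.isnan(s):
                continue
            assert s >= -1e-12
            assert s == go_similarity(cy, cx, dag, probs)


class TestCoexpression:
    def test_duplicate_profiles_fully_enriched(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        expr = ExpressionMatrix(
            genes=["a", "b", "c"],
            samples=[f"s{i}" for i in range(20)],
            values=np.vstack([base, base, rng.normal(size=20)]),
        )
        res = coexpression_enrichment(
            [("a", "b")], expr, n_boot=0, n_random=0, seed=1
        )
        assert res.observed == 1.0
        assert res.bootstrap_ci is None and res.null_samples == []

    def test_iid_noise_within_null_ci(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(30)]
        expr = ExpressionMatrix(
            genes=genes,
            samples=[f"s{i}" for i in range(40)],
            values=rng.normal(size=(30, 40)),
        )
        edges = [(genes[i], genes[i + 1]) for i in range(0, 28, 2)]
        res = coexpression_enrichment(edges, expr, n_boot=50, n_random=50, seed=2)
        lo, hi = res.null_ci()
        assert lo - 0.15 <= res.observed <= hi + 0.15

    def test_planted_coexpression_exceeds_null(self, sim_bundle):
        edges = sorted(sim_bundle["interactions"].pairs)[:120]
        res = coexpression_enrichment(
            edges, sim_bundle["expression"], n_boot=50, n_random=50, seed=3
        )
        assert res.observed > res.null_ci()[1]

    def test_too_few_samples_rejected(self):
        expr = ExpressionMatrix(
            genes=["a", "b"], samples=["s1", "s2"], values=[[1, 2], [2, 1]]
        )
        with pytest.raises(ValueError):
            coexpression_enrichment([("a", "b")], expr)


class TestFunctionalSimilarityNull:
    def test_null_replicates_preserve_degree(self, sim_bundle):
        edges = sorted(sim_bundle["interactions"].pairs)[:100]
        ann = sim_bundle["go_annotations"]
        res = functional_similarity_null(
            edges, ann, measure="kegg", n_random=20, seed=4
        )
        assert len(res.null_samples) == 20
        assert res.null_range is not None

    def test_planted_go_coherence_exceeds_null(self, sim_bundle):
        edges = sorted(sim_bundle["interactions"].pairs)[:150]
        res = functional_similarity_null(
            edges,
            sim_bundle["go_annotations"],
            measure="go",
            dag=sim_bundle["ontology"],
            n_random=30,
            seed=5,
        )
        assert res.exceeds_null_range

    def test_empty_after_restriction_rejected(self):
        with pytest.raises(ValueError):
            functional_similarity_null([("a", "b")], {"a": set(), "b": set()})

    def test_low_power_warning(self, sim_bundle):
        edges = sorted(sim_bundle["interactions"].pairs)[:50]
        with pytest.warns(UserWarning, match="low-power"):
            functional_similarity_null(
                edges, sim_bundle["go_annotations"], n_random=2, seed=6
            )
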