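"""Training-set sampling, forest training and all-pairs prediction."""

import numpy as np
import pytest

from ppidom.domain_odds import odds_from_interactions
from ppidom.evaluation import roc_auc
from ppidom.feature_builder import build_design_matrix
from ppidom.io_formats import InteractionSet, canonical_pair
from ppidom.rf_classifier import (
    PredictionSet,
    TrainingConfig,
    enumerate_candidate_pairs,
    predict_pairs,
    read_predictions,
    sample_training_sets,
    train,
    write_predictions,
)


@pytest.fixture(scope="module")
def trained_world(sim_bundle):
    """Forest trained on the shared synthetic world (scaled-down sampling)."""
    cfg = TrainingConfig(
        n_pos_train=250, n_neg_random=2500, n_neg_spiked=100, n_trees=150, seed=5
    )
    odds = odds_from_interactions(sim_bundle["interactions"], sim_bundle["proteome"])
    pos, neg = sample_training_sets(
        sim_bundle["interactions"], sim_bundle["proteome"], None, cfg
    )
    X, y, _, names = build_design_matrix(
        pos + neg,
        [1] * len(pos) + [0] * len(neg),
        sim_bundle["proteome_map"],
        odds,
        sim_bundle["domine"],
    )
    forest = train(X, y, cfg, names)
    return {"forest": forest, "odds": odds, "cfg": cfg, "X": X, "y": y,
            "names": names, "pos": pos, "neg": neg}


class TestSampling:
    def test_counts_and_disjointness(self, sim_bundle):
        cfg = TrainingConfig(
            n_pos_train=100, n_neg_random=500, n_neg_spiked=50, n_trees=10, seed=1
        )
        pos, neg = sample_training_sets(
            sim_bundle["interactions"], sim_bundle["proteome"], None, cfg
        )
        assert len(pos) == 100 and len(neg) == 550
        assert not set(pos) & set(neg)
        assert len(set(neg)) == len(neg)
        for pair in neg:
            assert pair not in sim_bundle["interactions"].pairs

    def test_exclusions_respected(self, sim_bundle):
        cfg = TrainingConfig(
            n_pos_train=50, n_neg_random=300, n_neg_spiked=30, n_trees=10, seed=2
        )
        ids = sorted(sim_bundle["proteome_map"])
        exclusions = InteractionSet()
        for i in range(0, 60, 2):
            pair = canonical_pair(ids[i], ids[i + 1])
            if pair not in sim_bundle["interactions"].pairs:
                exclusions.pairs.add(pair)
        _, neg = sample_training_sets(
            sim_bundle["interactions"], sim_bundle["proteome"], exclusions, cfg
        )
        assert not set(neg) & exclusions.pairs

    def test_degree_proportional_spike(self, sim_bundle):
        """A protein in ~10x more positive pairs should be drawn roughly 10x
        more often as a spiked-negative endpoint."""
        cfg = TrainingConfig(
            n_pos_train=100, n_neg_random=1, n_neg_spiked=3000, n_trees=10, seed=3
        )
        _, neg = sample_training_sets(
            sim_bundle["interactions"], sim_bundle["proteome"], None, cfg
        )
        spiked = neg[1:]
        degree = {}
        for a, b in sim_bundle["interactions"].pairs:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        counts = {}
        for a, b in spiked:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        high = [p for p, d in degree.items() if d >= 10]
        low = [p for p, d in degree.items() if d == 1]
        if high and low:
            mean_high = np.mean([counts.get(p, 0) for p in high])
            mean_low = np.mean([counts.get(p, 0) for p in low])
            assert mean_high > 3 * max(mean_low, 0.5)

    def test_deterministic_under_seed(self, sim_bundle):
        cfg = TrainingConfig(
            n_pos_train=50, n_neg_random=200, n_neg_spiked=20, n_trees=10, seed=4
        )
        s1 = sample_training_sets(
            sim_bundle["interactions"], sim_bundle["proteome"], None, cfg
        )
        s2 = sample_training_sets(
            sim_bundle["interactions"], sim_bundle["proteome"], None, cfg
        )
        assert s1 == s2

    def test_paper_default_counts(self):
        cfg = TrainingConfig()
        assert (cfg.n_pos_train, cfg.n_neg_random, cfg.n_neg_spiked, cfg.n_trees) == (
            1330, 101300, 1300, 400,
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(n_trees=0)


class TestTraining:
    def test_single_class_rejected(self, trained_world):
        with pytest.raises(ValueError):
            train(
                trained_world["X"][:10],
                np.zeros(10, dtype=int),
                trained_world["cfg"],
                trained_world["names"],
            )

    def test_feature_importances_exported(self, trained_world):
        imp = trained_world["forest"].feature_importances()
        assert len(imp) == len(trained_world["names"])
        assert all(v >= 0 for _, v in imp)
        # Domain-derived features carry the planted signal.
        top10 = {name for name, _ in imp[:10]}
        assert top10 & {"lod_sum", "lod_max", "n_pairs_scored", "domine_max_conf",
                        "n_domine_interacting", "lod_min_ceil0", "n_pairs_unscored"}

    def test_permuted_labels_auc_near_half(self, sim_bundle, trained_world):
        rng = np.random.default_rng(6)
        y_perm = rng.permutation(trained_world["y"])
        if y_perm.min() == y_perm.max():
            pytest.skip("degenerate permutation")
        cfg = TrainingConfig(n_pos_train=1, n_neg_random=1, n_neg_spiked=1,
                             n_trees=100, seed=7)
        X = trained_world["X"]
        n = len(y_perm)
        half = n // 2
        forest = train(X[:half], y_perm[:half], cfg, trained_world["names"])
        pos_col = list(forest.model.classes_).index(1)
        probs = forest.model.predict_proba(X[half:])[:, pos_col]
        auc = roc_auc(list(zip(probs.tolist(), y_perm[half:].tolist())))
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_same_seed_identical_predictions(self, trained_world, sim_bundle):
        cfg = trained_world["cfg"]
        forest2 = train(trained_world["X"], trained_world["y"], cfg,
                        trained_world["names"])
        p1 = trained_world["forest"].model.predict_proba(trained_world["X"][:50])
        p2 = forest2.model.predict_proba(trained_world["X"][:50])
        assert (p1 == p2).all()


class TestPrediction:
    def test_candidate_enumeration_includes_self_pairs(self):
        ids = ["a", "b", "c"]
        cand = enumerate_candidate_pairs(ids)
        assert len(cand) == 3 * 4 // 2
        assert ("a", "a") in cand

    def test_thread_count_invariance(self, trained_world, sim_bundle):
        cand = enumerate_candidate_pairs(sorted(sim_bundle["proteome_map"])[:40])
        kw = dict(
            proteome=sim_bundle["proteome_map"],
            odds=trained_world["odds"],
            domine=sim_bundle["domine"],
            threshold=0.0,
            chunk_size=100,
        )
        p1, _ = predict_pairs(trained_world["forest"], cand, threads=1, **kw)
        p4, _ = predict_pairs(trained_world["forest"], cand, threads=4, **kw)
        assert p1.scores == p4.scores

    def test_score_symmetry(self, trained_world, sim_bundle):
        ids = sorted(sim_bundle["proteome_map"])[:10]
        fwd = [(ids[i], ids[j]) for i in range(5) for j in range(5, 10)]
        rev = [(b, a) for a, b in fwd]
        kw = dict(
            proteome=sim_bundle["proteome_map"],
            odds=trained_world["odds"],
            domine=sim_bundle["domine"],
            threshold=0.0,
        )
        pf, _ = predict_pairs(trained_world["forest"], fwd, **kw)
        pr, _ = predict_pairs(trained_world["forest"], rev, **kw)
        assert pf.scores == pr.scores

    def test_threshold_nesting(self, trained_world, sim_bundle):
        cand = enumerate_candidate_pairs(sorted(sim_bundle["proteome_map"])[:60])
        preds, _ = predict_pairs(
            trained_world["forest"], cand, sim_bundle["proteome_map"],
            trained_world["odds"], sim_bundle["domine"], threshold=0.0,
        )
        views = [preds.at_threshold(t).pairs() for t in (0.55, 0.65, 0.75, 0.85)]
        for tighter, looser in zip(views[1:], views[:-1]):
            assert tighter.issubset(looser)

    def test_unknown_protein_skipped_with_count(self, trained_world, sim_bundle):
        cand = [("GHOST1", "GHOST2"), tuple(sorted(sim_bundle["proteome_map"])[:2])]
        preds, n_skipped = predict_pairs(
            trained_world["forest"], cand, sim_bundle["proteome_map"],
            trained_world["odds"], sim_bundle["domine"], threshold=0.0,
        )
        assert n_skipped == 1 and len(preds) == 1

    def test_raising_threshold_view_only(self, trained_world):
        ps = PredictionSet(scores={("a", "b"): 0.7, ("c", "d"): 0.9}, threshold=0.5)
        assert ps.at_threshold(0.8).pairs() == {("c", "d")}
        with pytest.raises(ValueError):
            ps.at_threshold(0.4)


def test_predictions_round_trip(tmp_path):
    ps = PredictionSet(scores={("a", "b"): 0.7251234, ("c", "d"): 0.9}, threshold=0.55)
    write_predictions(ps, tmp_path / "p.tsv")
    back = read_predictions(tmp_path / "p.tsv")
    assert back.scores == ps.scores and back.threshold == ps.threshold
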