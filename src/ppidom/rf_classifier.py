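"""Random-forest training and whole-proteome pair scoring.

Training uses a heavily unbalanced sampling protocol: a fixed number of known
interacting pairs as positives, a large uniform draw of non-interacting pairs
as negatives, plus a "spiked" negative subset whose endpoints are sampled in
proportion to their representation among the interacting pairs — this guards
against the forest learning to recognise the localization profile of
well-studied proteins instead of pairwise compatibility.  Every pair enters
the design matrix twice (forward and localization-reversed), and prediction
scores both orientations, taking the maximum, so the thresholded output is
the union of the two orientations' calls at every cut-off.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from sklearn.ensemble import RandomForestClassifier

from .domain_odds import DomainOddsTable
from .feature_builder import build_design_matrix
from .io_formats import DominTable, InteractionSet, ProteinRecord, canonical_pair

__all__ = [
    "TrainingConfig",
    "TrainedForest",
    "PredictionSet",
    "sample_training_sets",
    "train",
    "predict_pairs",
    "enumerate_candidate_pairs",
]


@dataclass
class TrainingConfig:
    """Sampling and forest sizes; the defaults reproduce the published
    protocol (1,330 positives, 101,300 uniform negatives, 1,300 spiked
    negatives, 400 fully-grown trees)."""

    n_pos_train: int = 1330
    n_neg_random: int = 101300
    n_neg_spiked: int = 1300
    n_trees: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pos_train", "n_neg_random", "n_neg_spiked", "n_trees"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainedForest:
    model: RandomForestClassifier
    feature_manifest: list[str]
    config: TrainingConfig
    provenance: dict = field(default_factory=dict)

    def feature_importances(self) -> list[tuple[str, float]]:
        imp = self.model.feature_importances_
        return sorted(zip(self.feature_manifest, imp), key=lambda t: -t[1])


@dataclass
class PredictionSet:
    """Map from unordered protein pair to confidence in [0, 1]."""

    scores: dict[tuple[str, str], float] = field(default_factory=dict)
    threshold: float = 0.0

    def at_threshold(self, cutoff: float) -> "PredictionSet":
        if cutoff < self.threshold:
            raise ValueError(
                f"cannot lower the threshold below {self.threshold} (pairs "
                "under it were discarded)"
            )
        return PredictionSet(
            scores={p: s for p, s in self.scores.items() if s >= cutoff},
            threshold=cutoff,
        )

    def pairs(self) -> set[tuple[str, str]]:
        return set(self.scores)

    def lookup(self, a: str, b: str) -> float | None:
        return self.scores.get(canonical_pair(a, b))

    def __len__(self) -> int:
        return len(self.scores)


def sample_training_sets(
    positives: InteractionSet,
    proteome: list[ProteinRecord],
    exclusions: InteractionSet | None,
    cfg: TrainingConfig,
    retry_factor: int = 200,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Draw the positive and negative training pairs.

    Positives: ``n_pos_train`` pairs sampled without replacement from the
    known interactions.  Negatives: ``n_neg_random`` unordered pairs of
    distinct proteins drawn uniformly and ``n_neg_spiked`` pairs whose
    endpoints are drawn in proportion to each protein's degree among the
    positive interactions, all rejected against positives, exclusions and one
    another.
    """
    rng = np.random.default_rng(cfg.seed)
    forbidden = set(positives.pairs)
    if exclusions:
        overlap = positives.pairs & exclusions.pairs
        if overlap:
            raise ValueError(
                f"{len(overlap)} positive pair(s) also listed as exclusions"
            )
        forbidden |= exclusions.pairs
    pos_pool = sorted(positives.pairs)
    if cfg.n_pos_train > len(pos_pool):
        raise ValueError(
            f"n_pos_train={cfg.n_pos_train} exceeds the {len(pos_pool)} "
            "available positive pairs"
        )
    pos_idx = rng.choice(len(pos_pool), size=cfg.n_pos_train, replace=False)
    pos_pairs = [pos_pool[i] for i in sorted(pos_idx.tolist())]

    ids = sorted(p.protein_id for p in proteome)
    n = len(ids)
    if n * (n - 1) // 2 < cfg.n_neg_random + cfg.n_neg_spiked + len(forbidden):
        raise ValueError("proteome too small to draw the requested negatives")
    taken: set[tuple[str, str]] = set()

    def draw(n_wanted: int, weights: np.ndarray | None) -> list[tuple[str, str]]:
        out: list[tuple[str, str]] = []
        budget = retry_factor * max(n_wanted, 1)
        while len(out) < n_wanted:
            if budget <= 0:
                raise RuntimeError(
                    "negative sampling exhausted its retry budget; reduce the "
                    "spike count or enlarge the proteome"
                )
            budget -= 1
            if weights is None:
                i, j = rng.integers(0, n, size=2)
            else:
                i, j = rng.choice(n, size=2, p=weights)
            if i == j:
                continue
            pair = canonical_pair(ids[i], ids[j])
            if pair in forbidden or pair in taken:
                continue
            taken.add(pair)
            out.append(pair)
        return out

    neg_pairs = draw(cfg.n_neg_random, None)
    # Endpoint weights proportional to degree within the positive set.
    degree = {pid: 0 for pid in ids}
    for a, b in positives.pairs:
        if a in degree:
            degree[a] += 1
        if b in degree:
            degree[b] += 1
    w = np.array([degree[pid] for pid in ids], dtype=float)
    if w.sum() <= 0:
        raise ValueError("no positive-set protein resolvable in the proteome")
    neg_pairs += draw(cfg.n_neg_spiked, w / w.sum())
    return pos_pairs, neg_pairs


def train(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: TrainingConfig,
    feature_manifest: list[str],
    provenance: dict | None = None,
) -> TrainedForest:
    """Fit the forest: ``cfg.n_trees`` fully grown (unpruned) trees."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    model = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_depth=None,
        min_samples_leaf=1,
        random_state=cfg.seed,
        n_jobs=1,
    )
    model.fit(features, labels)
    return TrainedForest(
        model=model,
        feature_manifest=list(feature_manifest),
        config=cfg,
        provenance=provenance or {},
    )


def enumerate_candidate_pairs(protein_ids) -> list[tuple[str, str]]:
    """All n(n+1)/2 unordered pairs (self-pairs included), sorted."""
    ids = sorted(protein_ids)
    return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i, len(ids))]


def _score_chunk(
    forest: TrainedForest,
    chunk: list[tuple[str, str]],
    proteome: dict[str, ProteinRecord],
    odds: DomainOddsTable,
    domine: DominTable,
    combine: str,
) -> np.ndarray:
    X, _, _, names = build_design_matrix(chunk, None, proteome, odds, domine)
    if names != forest.feature_manifest:
        raise ValueError(
            "feature manifest mismatch between the trained forest and the "
            "supplied tables"
        )
    pos_col = list(forest.model.classes_).index(1)
    prob = forest.model.predict_proba(X)[:, pos_col]
    fwd, rev = prob[0::2], prob[1::2]
    if combine == "max":
        return np.maximum(fwd, rev)
    if combine == "mean":
        return (fwd + rev) / 2.0
    raise ValueError(f"unknown combine rule {combine!r}")


def predict_pairs(
    forest: TrainedForest,
    candidate_pairs: list[tuple[str, str]],
    proteome: list[ProteinRecord] | dict[str, ProteinRecord],
    odds: DomainOddsTable,
    domine: DominTable,
    threshold: float = 0.5,
    threads: int = 1,
    combine: str = "max",
    chunk_size: int = 2000,
) -> tuple[PredictionSet, int]:
    """Score candidate pairs in both orientations and keep those at or above
    ``threshold``.

    The final confidence is the union rule over orientations (max of the
    forward and reversed probabilities by default).  The candidate list is
    partitioned deterministically into chunks; the result is independent of
    ``threads``.  Pairs naming an unknown protein are skipped and counted.
    Returns (prediction set, number of skipped pairs).
    """
    if isinstance(proteome, list):
        proteome = {p.protein_id: p for p in proteome}
    known: list[tuple[str, str]] = []
    n_skipped = 0
    seen: set[tuple[str, str]] = set()
    for a, b in candidate_pairs:
        pair = canonical_pair(a, b)
        if pair in seen:
            continue
        seen.add(pair)
        if a in proteome and b in proteome:
            known.append(pair)
        else:
            n_skipped += 1
    known.sort()
    if not known:
        return PredictionSet(threshold=threshold), n_skipped
    chunks = [known[i : i + chunk_size] for i in range(0, len(known), chunk_size)]
    if threads <= 1 or len(chunks) == 1:
        scored = [
            _score_chunk(forest, c, proteome, odds, domine, combine) for c in chunks
        ]
    else:
        scored = Parallel(n_jobs=threads, prefer="threads")(
            delayed(_score_chunk)(forest, c, proteome, odds, domine, combine)
            for c in chunks
        )
    scores: dict[tuple[str, str], float] = {}
    for chunk, probs in zip(chunks, scored):
        for pair, s in zip(chunk, probs):
            if s >= threshold:
                scores[pair] = float(s)
    return PredictionSet(scores=scores, threshold=threshold), n_skipped


def write_predictions(predictions: PredictionSet, path) -> None:
    """protein1, protein2, confidence rows (sorted, deterministic)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#threshold={repr(float(predictions.threshold))}\n")
        for (a, b) in sorted(predictions.scores):
            fh.write(f"{a}\t{b}\t{repr(predictions.scores[(a, b)])}\n")


def read_predictions(path) -> PredictionSet:
    threshold = 0.0
    scores: dict[tuple[str, str], float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#threshold="):
                threshold = float(line.split("=", 1)[1])
                continue
            if not line or line.startswith("#"):
                continue
            a, b, s = line.split("\t")
            scores[canonical_pair(a, b)] = float(s)
    return PredictionSet(scores=scores, threshold=threshold)


def digest_table(path) -> str:
    """Short content digest used for provenance bookkeeping."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()[:16]
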