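"""Fixed-order numeric feature vectors for ordered protein pairs.

The domain block of the vector is order-invariant (it is computed on the
unique unordered domain combinations of the pair's cross product); the
localization block is order-sensitive, which is why training and prediction
duplicate every pair in a forward and a reversed (localization-swapped)
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .domain_odds import DomainOddsTable, _cross_combinations
from .io_formats import DominTable, ProteinRecord, canonical_pair

__all__ = ["PairFeatureVector", "build_pair_features", "build_design_matrix",
           "DOMAIN_FEATURE_NAMES", "feature_names"]

DOMAIN_FEATURE_NAMES: tuple[str, ...] = (
    "lod_sum",
    "lod_max",
    "lod_min_ceil0",
    "n_pairs_unscored",
    "n_pairs_scored",
    "n_domine_interacting",
    "domine_max_conf",
)


@dataclass
class PairFeatureVector:
    lod_sum: float
    lod_max: float
    lod_min_ceil0: float
    n_pairs_unscored: int
    n_pairs_scored: int
    n_domine_interacting: int
    domine_max_conf: float
    loc_a: dict[str, float]
    loc_b: dict[str, float]

    def domain_block(self) -> tuple[float, ...]:
        return (
            self.lod_sum,
            self.lod_max,
            self.lod_min_ceil0,
            float(self.n_pairs_unscored),
            float(self.n_pairs_scored),
            float(self.n_domine_interacting),
            self.domine_max_conf,
        )

    def to_row(self, loc_schema: list[str]) -> list[float]:
        return [
            *self.domain_block(),
            *(self.loc_a[n] for n in loc_schema),
            *(self.loc_b[n] for n in loc_schema),
        ]


def feature_names(loc_schema: list[str]) -> list[str]:
    """The frozen feature order: domain block, then slot-A and slot-B
    localization blocks."""
    return [
        *DOMAIN_FEATURE_NAMES,
        *(f"loc_a_{n}" for n in loc_schema),
        *(f"loc_b_{n}" for n in loc_schema),
    ]


def build_pair_features(
    a: ProteinRecord,
    b: ProteinRecord,
    odds: DomainOddsTable,
    domine: DominTable,
    allow_missing_loc: bool = False,
    loc_schema: list[str] | None = None,
) -> PairFeatureVector:
    """Score one ordered protein pair against the odds and DOMINE tables.

    Domain features: over the unique unordered cross combinations of the two
    proteins' domains — the sum of the LOD scores of the combinations present
    in the odds table, the highest such score, the lowest such score ceilinged
    at 0 (never exceeds 0; 0 when all scored LODs are positive), the counts of
    unscored and scored combinations, and the DOMINE hit count and maximum
    confidence.  Proteins with no domains yield an all-zero domain block.
    """
    # Sorted combo order keeps floating-point sums bit-identical between
    # (a, b) and (b, a).
    combos = sorted(_cross_combinations(a.domains, b.domains))
    scored = [odds.lod[c] for c in combos if c in odds.lod]
    n_scored = len(scored)
    n_unscored = len(combos) - n_scored
    lod_sum = float(sum(scored))
    lod_max = float(max(scored)) if scored else 0.0
    lod_min_ceil0 = min(0.0, float(min(scored))) if scored else 0.0
    domine_hits = [
        conf for c in combos if (conf := domine.lookup(*c)) is not None
    ]
    loc_a, loc_b = a.localization, b.localization
    if loc_a is None or loc_b is None:
        if not allow_missing_loc:
            missing = a.protein_id if loc_a is None else b.protein_id
            raise ValueError(
                f"protein {missing!r} has no localization vector "
                "(use allow_missing_loc to zero-fill)"
            )
        if loc_schema is None:
            template = loc_a or loc_b
            if template is None:
                raise ValueError(
                    "cannot zero-fill localization without a schema: both "
                    f"{a.protein_id!r} and {b.protein_id!r} lack vectors"
                )
            loc_schema = list(template.keys())
        zero = {n: 0.0 for n in loc_schema}
        present_a = loc_a is not None
        present_b = loc_b is not None
        loc_a = dict(loc_a) if present_a else dict(zero)
        loc_b = dict(loc_b) if present_b else dict(zero)
        loc_a["_loc_present"] = float(present_a)
        loc_b["_loc_present"] = float(present_b)
    else:
        loc_a, loc_b = dict(loc_a), dict(loc_b)
    return PairFeatureVector(
        lod_sum=lod_sum,
        lod_max=lod_max,
        lod_min_ceil0=lod_min_ceil0,
        n_pairs_unscored=n_unscored,
        n_pairs_scored=n_scored,
        n_domine_interacting=len(domine_hits),
        domine_max_conf=float(max(domine_hits)) if domine_hits else 0.0,
        loc_a=loc_a,
        loc_b=loc_b,
    )


def build_design_matrix(
    pairs: list[tuple[str, str]],
    labels: list[int] | None,
    proteome: dict[str, ProteinRecord],
    odds: DomainOddsTable,
    domine: DominTable,
    allow_missing_loc: bool = False,
) -> tuple[np.ndarray, np.ndarray | None, list[tuple[tuple[str, str], str]], list[str]]:
    """Build the forward+reversed design matrix for a list of pairs.

    Each pair contributes two rows: forward (slot A = first protein) and
    reversed (localization blocks swapped).  Domain features are identical in
    the two rows because they are order-invariant.  Returns
    (matrix, labels or None, row_index of (pair, orientation), feature names).
    """
    if not pairs:
        raise ValueError("empty pair list")
    if labels is not None and len(labels) != len(pairs):
        raise ValueError("pairs and labels must have the same length")
    first = proteome[pairs[0][0]]
    schema: list[str] | None = None
    if first.localization is not None:
        schema = list(first.localization.keys())
    rows: list[list[float]] = []
    out_labels: list[int] = []
    row_index: list[tuple[tuple[str, str], str]] = []
    names: list[str] | None = None
    for k, (pa, pb) in enumerate(pairs):
        fv = build_pair_features(
            proteome[pa], proteome[pb], odds, domine,
            allow_missing_loc=allow_missing_loc, loc_schema=schema,
        )
        loc_schema = list(fv.loc_a.keys())
        if names is None:
            names = feature_names(loc_schema)
        rows.append(fv.to_row(loc_schema))
        # Reversed orientation: swap the localization blocks only.
        rev = PairFeatureVector(
            **{f: getattr(fv, f) for f in (
                "lod_sum", "lod_max", "lod_min_ceil0", "n_pairs_unscored",
                "n_pairs_scored", "n_domine_interacting", "domine_max_conf")},
            loc_a=fv.loc_b,
            loc_b=fv.loc_a,
        )
        rows.append(rev.to_row(loc_schema))
        row_index.append(((pa, pb), "forward"))
        row_index.append(((pa, pb), "reversed"))
        if labels is not None:
            out_labels.extend([labels[k], labels[k]])
    X = np.asarray(rows, dtype=float)
    y = np.asarray(out_labels, dtype=int) if labels is not None else None
    assert names is not None
    return X, y, row_index, names


def write_feature_matrix(X, row_index, names, path, labels=None) -> None:
    """Write a design matrix with its header manifest as TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        cols = ["protein_a", "protein_b", "orientation", *names]
        if labels is not None:
            cols.append("label")
        fh.write("\t".join(cols) + "\n")
        for i, ((pa, pb), orient) in enumerate(row_index):
            row = [pa, pb, orient, *(repr(float(v)) for v in X[i])]
            if labels is not None:
                row.append(str(int(labels[i])))
            fh.write("\t".join(row) + "\n")
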