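"""Pairwise domain log-of-odds scores from interacting protein pairs.

For every unordered domain pair (Dx, Dy) observed in at least one interacting
protein pair, the log-of-odds score

    LOD(Dx, Dy) = ln[ f(Dx, Dy) / (f(Dx) f(Dy)) ]

contrasts the observed frequency of the pair among interacting proteins with
the product of the marginal domain frequencies.  f(Dx, Dy) is the fraction of
all domain-pair observations contributed by (Dx, Dy); f(Dx) is the fraction of
per-protein domain occurrences contributed by Dx, counted over the set of
proteins that appear in at least one interaction (each protein contributes
each of its unique domains once, regardless of how many interactions it
joins).  Domain pairs never observed in an interacting protein pair are absent
from the table and score 0 on lookup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import InteractionSet, ProteinRecord, canonical_pair

__all__ = ["DomainOddsTable", "count_domain_pairs", "compute_lod", "holdout_split",
           "read_odds_table", "write_odds_table"]


@dataclass
class DomainOddsTable:
    pair_counts: dict[tuple[str, str], int]
    domain_counts: dict[str, int]
    total_pair_observations: int
    total_domain_observations: int
    lod: dict[tuple[str, str], float] = field(default_factory=dict)
    n_skipped_pairs: int = 0

    def lookup(self, a: str, b: str) -> float:
        """LOD for an unordered domain pair; exactly 0 when never observed."""
        return self.lod.get(canonical_pair(a, b), 0.0)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.lod


def _cross_combinations(
    domains_a: tuple[str, ...], domains_b: tuple[str, ...]
) -> set[tuple[str, str]]:
    """Unique unordered domain pairs from the cross product A x B."""
    return {canonical_pair(d, e) for d in domains_a for e in domains_b}


def count_domain_pairs(
    interactions: InteractionSet, proteome: list[ProteinRecord]
) -> tuple[dict[tuple[str, str], int], dict[str, int], tuple[int, int], int]:
    """Count domain-pair and domain occurrences over an interaction set.

    For each interacting pair (P, Q), every unique unordered cross combination
    of P's and Q's domains is incremented once.  Domain occurrences are counted
    over the set of proteins appearing in >= 1 resolvable interaction, each
    protein contributing each unique domain once.  Self-interactions are
    included.  Pairs with an unresolvable protein are skipped and counted.

    Returns (pair_counts, domain_counts, (n_pair_obs, n_domain_obs), n_skipped).
    """
    if not interactions.pairs:
        raise ValueError("cannot compute domain odds from an empty interaction set")
    index = {p.protein_id: p for p in proteome}
    pair_counts: dict[tuple[str, str], int] = {}
    interacting_proteins: set[str] = set()
    n_skipped = 0
    for a, b in interactions.pairs:
        ra, rb = index.get(a), index.get(b)
        if ra is None or rb is None:
            n_skipped += 1
            continue
        interacting_proteins.update((a, b))
        for combo in _cross_combinations(ra.domains, rb.domains):
            pair_counts[combo] = pair_counts.get(combo, 0) + 1
    domain_counts: dict[str, int] = {}
    for pid in interacting_proteins:
        for d in index[pid].domains:
            domain_counts[d] = domain_counts.get(d, 0) + 1
    totals = (sum(pair_counts.values()), sum(domain_counts.values()))
    return pair_counts, domain_counts, totals, n_skipped


def compute_lod(
    pair_counts: dict[tuple[str, str], int],
    domain_counts: dict[str, int],
    totals: tuple[int, int],
    n_skipped: int = 0,
) -> DomainOddsTable:
    """Turn count tables into a LOD table (natural log)."""
    n_pair_obs, n_domain_obs = totals
    if n_pair_obs <= 0 or n_domain_obs <= 0:
        raise ValueError("totals must be positive to compute LOD scores")
    lod: dict[tuple[str, str], float] = {}
    for (dx, dy), n_xy in pair_counts.items():
        f_xy = n_xy / n_pair_obs
        f_x = domain_counts[dx] / n_domain_obs
        f_y = domain_counts[dy] / n_domain_obs
        lod[(dx, dy)] = math.log(f_xy / (f_x * f_y))
    return DomainOddsTable(
        pair_counts=dict(pair_counts),
        domain_counts=dict(domain_counts),
        total_pair_observations=n_pair_obs,
        total_domain_observations=n_domain_obs,
        lod=lod,
        n_skipped_pairs=n_skipped,
    )


def odds_from_interactions(
    interactions: InteractionSet, proteome: list[ProteinRecord]
) -> DomainOddsTable:
    """Convenience: count then score in one call."""
    pair_counts, domain_counts, totals, n_skipped = count_domain_pairs(
        interactions, proteome
    )
    return compute_lod(pair_counts, domain_counts, totals, n_skipped)


def holdout_split(
    interactions: InteractionSet, n_test: int, seed: int
) -> tuple[InteractionSet, InteractionSet]:
    """Reserve ``n_test`` interactions for testing; the rest feed the odds
    counting.  Disjoint, reproducible under ``seed``."""
    pairs = sorted(interactions.pairs)
    if n_test >= len(pairs):
        raise ValueError(
            f"n_test={n_test} must be smaller than the interaction count {len(pairs)}"
        )
    rng = np.random.default_rng(seed)
    test_idx = set(rng.choice(len(pairs), size=n_test, replace=False).tolist())
    odds = InteractionSet(source_label=f"{interactions.source_label}:odds")
    test = InteractionSet(source_label=f"{interactions.source_label}:test")
    for i, p in enumerate(pairs):
        (test if i in test_idx else odds).pairs.add(p)
    return odds, test


def write_odds_table(table: DomainOddsTable, path) -> None:
    """Write the LOD table as domain1, domain2, lod, n_pair rows plus a
    counts sidecar header comment."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# total_pair_observations={table.total_pair_observations}"
            f"\ttotal_domain_observations={table.total_domain_observations}\n"
        )
        fh.write("#domain1\tdomain2\tlod\tn_pair\n")
        for (a, b) in sorted(table.lod):
            fh.write(f"{a}\t{b}\t{repr(table.lod[(a, b)])}\t{table.pair_counts[(a, b)]}\n")


def read_odds_table(path) -> DomainOddsTable:
    """Read a LOD table written by :func:`write_odds_table`.

    Count tables are only partially recoverable from the flat file (the
    per-domain counts are not serialised); the returned table carries the LOD
    map and pair counts, which is all prediction needs.
    """
    lod: dict[tuple[str, str], float] = {}
    pair_counts: dict[tuple[str, str], int] = {}
    totals = (0, 0)
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# total_pair_observations="):
                parts = dict(
                    kv.split("=") for kv in line[2:].split("\t") if "=" in kv
                )
                totals = (
                    int(parts["total_pair_observations"]),
                    int(parts["total_domain_observations"]),
                )
                continue
            if not line or line.startswith("#"):
                continue
            a, b, lod_s, n_s = line.split("\t")
            key = canonical_pair(a, b)
            lod[key] = float(lod_s)
            pair_counts[key] = int(n_s)
    return DomainOddsTable(
        pair_counts=pair_counts,
        domain_counts={},
        total_pair_observations=totals[0],
        total_domain_observations=totals[1],
        lod=lod,
    )
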