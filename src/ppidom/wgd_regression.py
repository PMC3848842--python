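"""Logistic regression of duplicate-gene retention on network topology.

The gene balance hypothesis predicts that genes with many interaction
partners — and especially partners that were themselves retained in duplicate
after a whole-genome duplication (WGD) — are preferentially retained, because
selection maintains stoichiometric balance among interacting products.  The
model is

    retained ~ log(degree centrality) + duplicated-neighbor fraction
               + log(degree centrality) : duplicated-neighbor fraction

fit with a logit link on genes with at least ``min_degree`` interactions in
the predicted network, with percentile confidence intervals from a
case-resampling bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import statsmodels.api as sm

from .graph_tools import degree_centrality

__all__ = [
    "DuplicationTable",
    "GlmFit",
    "duplicated_neighbor_fraction",
    "retention_design",
    "fit_retention_glm",
    "fit_logistic_bootstrap",
    "COEF_NAMES",
]

COEF_NAMES = ("intercept", "log_dc", "dup_neighbors", "log_dc:dup_neighbors")
CI_LEVELS = (0.95, 0.99, 0.999)


class DuplicationTable:
    """gene id -> 0/1 retention flag per WGD event label (free strings)."""

    def __init__(self, flags: dict[str, dict[str, int]]):
        # flags[event][gene] = 0/1
        self.flags: dict[str, dict[str, int]] = {}
        for event, table in flags.items():
            clean: dict[str, int] = {}
            for gene, v in table.items():
                if v not in (0, 1):
                    raise ValueError(
                        f"retention flag for {gene!r} under {event!r} must be 0/1"
                    )
                clean[gene] = int(v)
            self.flags[event] = clean

    def events(self) -> list[str]:
        return sorted(self.flags)

    def event(self, label: str) -> dict[str, int]:
        return self.flags[label]


@dataclass
class GlmFit:
    coefficients: dict[str, float]
    ci: dict[str, dict[float, tuple[float, float]]]
    stars: dict[str, str]
    boot_samples: np.ndarray
    n_obs: int
    n_boot: int
    n_redrawn: int = 0
    converged: bool = True
    notes: list[str] = field(default_factory=list)

    def summary_rows(self) -> list[dict]:
        rows = []
        for name in COEF_NAMES:
            row = {"coef": name, "estimate": self.coefficients[name],
                   "stars": self.stars[name]}
            for level in CI_LEVELS:
                lo, hi = self.ci[name][level]
                row[f"ci{level}_lo"] = lo
                row[f"ci{level}_hi"] = hi
            rows.append(row)
        return rows


def duplicated_neighbor_fraction(
    g: nx.Graph, flags: dict[str, int], gene: str
) -> float:
    """Fraction of a gene's network neighbors retained in duplicate.

    Neighbors without a flag count as not retained.
    """
    neighbors = list(g.neighbors(gene))
    if not neighbors:
        raise ValueError(
            f"gene {gene!r} is isolated; the retention model uses genes with "
            "at least one interaction"
        )
    return sum(flags.get(nb, 0) for nb in neighbors) / len(neighbors)


def retention_design(
    g: nx.Graph, flags: dict[str, int], min_degree: int = 1
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix (intercept, ln DC, DN, ln DC * DN) and response for all
    flagged genes with degree >= min_degree."""
    genes = sorted(gene for gene in flags if gene in g and g.degree(gene) >= min_degree)
    if not genes:
        raise ValueError("no flagged genes meet the degree filter")
    rows = []
    y = []
    for gene in genes:
        dc = degree_centrality(g, gene)
        dn = duplicated_neighbor_fraction(g, flags, gene)
        ldc = np.log(dc)
        rows.append([1.0, ldc, dn, ldc * dn])
        y.append(flags[gene])
    return np.asarray(rows), np.asarray(y, dtype=int), genes


def _fit_logit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    return np.asarray(res.params), bool(res.mle_retvals.get("converged", True))


def fit_logistic_bootstrap(
    X: np.ndarray,
    y: np.ndarray,
    n_boot: int = 10000,
    seed: int = 0,
    max_redraw_factor: int = 5,
) -> GlmFit:
    """Maximum-likelihood logistic fit with case-resampling percentile CIs.

    Bootstrap replicates resample rows with replacement; replicates whose
    resampled response is single-class are redrawn (counted, capped at
    ``max_redraw_factor * n_boot`` total draws).  A coefficient is starred
    (*, **, ***) when its 95/99/99.9% CI excludes 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both response classes must be present")
    params, converged = _fit_logit(X, y)
    n = len(y)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, X.shape[1]))
    n_redrawn = 0
    budget = max_redraw_factor * n_boot
    b = 0
    notes: list[str] = []
    while b < n_boot:
        if budget <= 0:
            raise RuntimeError("bootstrap redraw budget exhausted")
        budget -= 1
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.min() == yb.max():
            n_redrawn += 1
            continue
        try:
            boots[b], _ = _fit_logit(X[idx], yb)
        except Exception:  # perfect separation in a replicate
            n_redrawn += 1
            continue
        b += 1
    coefficients = dict(zip(COEF_NAMES, params.tolist()))
    ci: dict[str, dict[float, tuple[float, float]]] = {}
    stars: dict[str, str] = {}
    for k, name in enumerate(COEF_NAMES):
        ci[name] = {}
        star = ""
        for level, symbol in zip(CI_LEVELS, ("*", "**", "***")):
            lo, hi = np.percentile(
                boots[:, k], [(1 - level) / 2 * 100, (1 + level) / 2 * 100]
            )
            ci[name][level] = (float(lo), float(hi))
            if lo > 0 or hi < 0:
                star = symbol
        stars[name] = star
    if not converged:
        notes.append("point-estimate fit did not report convergence")
    return GlmFit(
        coefficients=coefficients,
        ci=ci,
        stars=stars,
        boot_samples=boots,
        n_obs=n,
        n_boot=n_boot,
        n_redrawn=n_redrawn,
        converged=converged,
        notes=notes,
    )


def write_duplication(table: DuplicationTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#gene\tevent\tretained\n")
        for event in table.events():
            flags = table.event(event)
            for gene in sorted(flags):
                fh.write(f"{gene}\t{event}\t{flags[gene]}\n")


def read_duplication(path) -> DuplicationTable:
    from .io_formats import ParseError, _data_lines

    flags: dict[str, dict[str, int]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected gene, event, flag")
        gene, event, flag = (f.strip() for f in fields[:3])
        if flag not in ("0", "1"):
            raise ValueError(f"{path}:{lineno}: flag must be 0 or 1, got {flag!r}")
        flags.setdefault(event, {})[gene] = int(flag)
    return DuplicationTable(flags)


def fit_retention_glm(
    g: nx.Graph,
    dup: DuplicationTable,
    event: str,
    min_degree: int = 1,
    n_boot: int = 10000,
    seed: int = 0,
) -> GlmFit:
    """Fit the retention model for one WGD event on a predicted network.

    Two conventional fits are ``min_degree=1`` (all connected genes) and
    ``min_degree=10`` (genes whose duplicated-neighbor fraction is not forced
    to the endpoints {0, 1} by having a single neighbor).
    """
    X, y, _ = retention_design(g, dup.event(event), min_degree=min_degree)
    return fit_logistic_bootstrap(X, y, n_boot=n_boot, seed=seed)
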