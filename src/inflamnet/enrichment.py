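"""Gene-set over-representation, set-overlap tests and pathway activity.

Over-representation analysis (ORA) is a one-sided hypergeometric test of a
query gene list against GMT-defined gene sets; set overlap between two gene
lists uses a chi-square test on the 2x2 membership table with a Fisher exact
fallback when expected counts are small; per-sample pathway activity is an
ssGSEA-style weighted Kolmogorov-Smirnov running-sum statistic.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

logger = logging.getLogger(__name__)

ODDS_RATIO_CAP = 1e6


def read_gmt(path) -> dict[str, list[str]]:
    """Load a GMT file into {set name: member genes}, genes uppercased."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has < 3 fields")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = sorted({g.upper() for g in parts[2:] if g})
    return sets


def ora(
    query: set[str] | list[str],
    collection: dict[str, list[str]],
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a query gene set.

    For each term with m members in a universe of N genes and a query of n
    genes overlapping k members, p = P[X >= k] for X ~ Hypergeom(N, m, n).
    BH adjustment across terms; result sorted by adjusted then raw p.
    """
    universe = {g.upper() for g in universe}
    if not universe:
        raise ValueError("universe is empty")
    query = {g.upper() for g in query} & universe
    rows = []
    for name, members in collection.items():
        term = {g.upper() for g in members} & universe
        k = len(query & term)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(term), len(query)))
        rows.append(
            {
                "term": name,
                "overlap": k,
                "set_size": len(term),
                "query_size": len(query),
                "universe_size": len(universe),
                "pvalue": min(p, 1.0),
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["padj"] = bh_adjust(result["pvalue"].to_numpy())
        result = result.sort_values(["padj", "pvalue", "term"]).reset_index(drop=True)
    return result


def set_overlap_test(
    set_a: set[str] | list[str],
    set_b: set[str] | list[str],
    universe: set[str] | list[str],
) -> tuple[float, float]:
    """Association between two gene sets within a universe.

    Builds the 2x2 membership table and applies a chi-square test with
    continuity correction; when any expected cell is 5 or fewer (Cochran's
    small-count regime), a one-sided Fisher exact test (alternative: greater,
    i.e. over-overlap) substitutes.  The odds ratio is capped at 1e6 when a
    margin cell is zero.
    """
    universe = {g.upper() for g in universe}
    if not universe:
        raise ValueError("universe is empty")
    a = {g.upper() for g in set_a} & universe
    b = {g.upper() for g in set_b} & universe
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(universe) - n11 - n10 - n01
    table = np.array([[n11, n10], [n01, n00]], dtype=float)

    if n10 * n01 == 0:
        odds = ODDS_RATIO_CAP if n11 * n00 > 0 else (
            0.0 if n11 == 0 and n10 * n01 > 0 else ODDS_RATIO_CAP
        )
        if n11 * n00 == 0 and n10 * n01 == 0:
            odds = 1.0  # fully degenerate table
    else:
        odds = (n11 * n00) / (n10 * n01)

    # degenerate margins (empty set or set == universe) carry no information
    if min(table.sum(axis=0).min(), table.sum(axis=1).min()) == 0:
        return float(odds), 1.0

    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected <= 5).any():
        p = float(stats.fisher_exact(table.astype(int), alternative="greater")[1])
    else:
        p = float(stats.chi2_contingency(table, correction=True)[1])
    return float(odds), p


def pathway_activity(
    expr: pd.DataFrame,
    collection: dict[str, list[str]],
    weight_exponent: float = 0.25,
    min_set_size: int = 5,
) -> pd.DataFrame:
    """Single-sample pathway activity scores (ssGSEA-style).

    Per sample, genes are ranked by expression (rank 1 = lowest); the score of
    a gene set is the maximum-deviation value of a weighted running sum that
    steps up by rank**weight_exponent (normalized) at member genes and down by
    1/(N - |S|) elsewhere, walking from the highest-expressed gene downward.
    Depends on ranks only, hence invariant to monotone transforms.  Sets with
    fewer than ``min_set_size`` measured genes are skipped with a warning.
    """
    genes = expr.index.to_numpy()
    n = len(genes)
    memberships = {}
    for name, members in collection.items():
        mask = expr.index.isin({g.upper() for g in members})
        if mask.sum() < min_set_size:
            logger.warning(
                "gene set %s has %d measured genes (< %d); skipped",
                name,
                int(mask.sum()),
                min_set_size,
            )
            continue
        memberships[name] = mask
    scores = pd.DataFrame(
        np.nan, index=list(memberships), columns=expr.columns, dtype=float
    )
    values = expr.to_numpy(dtype=float)
    for j, sample in enumerate(expr.columns):
        ranks = stats.rankdata(values[:, j], method="average")
        order = np.argsort(-ranks, kind="mergesort")  # descending expression
        weights = ranks ** weight_exponent
        for name, mask in memberships.items():
            m = mask[order]
            w = weights[order]
            inc = np.where(m, w, 0.0)
            denom = inc.sum()
            miss = 1.0 / (n - m.sum())
            steps = inc / denom - np.where(m, 0.0, miss)
            running = np.cumsum(steps)
            scores.loc[name, sample] = float(running[np.argmax(np.abs(running))])
    return scores
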