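"""Two-group differential expression against normal tissue.

Each disease contrast is a per-gene Welch t-test on log2-normalized values
with Benjamini-Hochberg correction.  A gene is called ``up`` when its linear
fold change exceeds 1.5 (|log2FC| > log2(1.5), strict) and the adjusted
p-value is below 0.05 (strict); ``down`` symmetrically; otherwise ``ns``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

FC_THRESHOLD = 1.5
PADJ_THRESHOLD = 0.05

LOG2_FC_THRESHOLD = np.log2(FC_THRESHOLD)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1.

    adj p_(i) = min over j >= i of p_(j) * n / j, in the order of the input.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def _call(log2fc: np.ndarray, padj: np.ndarray) -> np.ndarray:
    call = np.full(log2fc.shape, "ns", dtype=object)
    sig = padj < PADJ_THRESHOLD
    call[sig & (log2fc > LOG2_FC_THRESHOLD)] = "up"
    call[sig & (log2fc < -LOG2_FC_THRESHOLD)] = "down"
    return call


def de_test(
    expr: pd.DataFrame, group_a: list[str], group_b: list[str]
) -> pd.DataFrame:
    """Welch t-test per gene between two sample groups on log2 values.

    log2FC = mean(group_a) - mean(group_b).  Genes with zero variance in both
    groups get p = 1 and call ``ns``.  Returns a DataFrame indexed by gene
    with columns log2fc, pvalue, padj, call.
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    for g in group_a + group_b:
        if g not in expr.columns:
            raise ValueError(f"sample {g!r} not in expression matrix")
    a = expr[group_a].to_numpy(dtype=float)
    b = expr[group_b].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(degenerate | ~np.isfinite(p), 1.0, p)
    padj = bh_adjust(p)
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": p, "padj": padj, "call": _call(log2fc, padj)},
        index=expr.index,
    )


def resolve_group(samples: pd.DataFrame, label: str) -> list[str]:
    """Resolve a group label to sample ids.

    Labels may be a category (NB, IBT, Fibro, DCIS, IDC), an IDC subtype
    (LuminalA, LuminalB, Her2, TNBC) or ``ER-`` = Her2 union TNBC (the
    estrogen-receptor-negative tumors).
    """
    if label == "ER-":
        mask = samples["subtype"].isin(["Her2", "TNBC"])
    elif label in set(samples["category"]):
        mask = samples["category"] == label
    else:
        mask = samples["subtype"] == label
    return list(samples.index[mask])


DEFAULT_CONTRASTS = [
    ("IBT_vs_NB", "IBT", "NB"),
    ("ERneg_vs_NB", "ER-", "NB"),
    ("Her2_vs_NB", "Her2", "NB"),
    ("TNBC_vs_NB", "TNBC", "NB"),
]


def run_contrasts(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    contrasts: list[tuple[str, str, str]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Run a list of named two-group contrasts; defaults are the four disease
    groups versus normal breast (IBT, ER-, Her2, TNBC vs NB)."""
    if contrasts is None:
        contrasts = DEFAULT_CONTRASTS
    out = {}
    for name, lab_a, lab_b in contrasts:
        ga = resolve_group(samples, lab_a)
        gb = resolve_group(samples, lab_b)
        if not ga or not gb:
            raise ValueError(f"contrast {name!r}: empty group ({lab_a!r} or {lab_b!r})")
        out[name] = de_test(expr, ga, gb)
    return out


def de_gene_union(results: dict[str, pd.DataFrame]) -> list[str]:
    """Union of genes called up or down in any contrast, in matrix order."""
    genes: set[str] = set()
    order: list[str] = []
    for res in results.values():
        for g in res.index[res["call"] != "ns"]:
            if g not in genes:
                genes.add(g)
                order.append(g)
    return order
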