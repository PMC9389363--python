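"""Cell-type fraction estimation from a signature matrix.

A mixture sample is modelled as a non-negative linear combination of the
columns of a linear-scale signature matrix (immune LM22-format, 22 cell
types, or a 7-subtype erythroid signature).  Fractions are obtained by
non-negative least squares restricted to shared signature genes, then
renormalized to sum to one; the reconstruction RMSE is reported per sample.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

logger = logging.getLogger(__name__)


def read_signature(path) -> pd.DataFrame:
    """Load a signature TSV (first column gene symbol, one column per type)."""
    sig = pd.read_csv(path, sep="\t", index_col=0)
    sig.index = sig.index.astype(str).str.upper()
    if (sig.to_numpy() < 0).any():
        raise ValueError("signature matrix contains negative values")
    if sig.shape[1] < 2:
        raise ValueError("signature matrix needs at least 2 cell types")
    return sig


def estimate_fractions(
    mixture: pd.DataFrame, signature: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample NNLS deconvolution against a signature matrix.

    Requires linear-scale input (log-like matrices with max < 50 are
    rejected) and at least 50% of signature genes present in the mixture.
    Returns (fractions: samples x cell types, each row summing to 1;
    per-sample reconstruction RMSE).
    """
    if float(np.nanmax(mixture.to_numpy())) < 50:
        raise ValueError(
            "mixture looks log-transformed (max < 50); deconvolution requires "
            "linear-scale expression"
        )
    shared = signature.index.intersection(mixture.index)
    if len(shared) < 0.5 * len(signature):
        raise ValueError(
            f"only {len(shared)}/{len(signature)} signature genes found in mixture"
        )
    a = signature.loc[shared].to_numpy(dtype=float)
    fractions = {}
    rmse = {}
    for s in mixture.columns:
        y = mixture.loc[shared, s].to_numpy(dtype=float)
        if not y.any():
            raise ValueError(f"sample {s!r} is all zero over signature genes")
        coef, _ = nnls(a, y)
        total = coef.sum()
        if total == 0:
            raise ValueError(f"sample {s!r}: NNLS returned the zero solution")
        fractions[s] = coef / total
        rmse[s] = float(np.sqrt(np.mean((a @ coef - y) ** 2)))
    frac = pd.DataFrame.from_dict(
        fractions, orient="index", columns=signature.columns
    )
    return frac, pd.Series(rmse, name="rmse")


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_fractions(
    fractions: pd.DataFrame,
    samples: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
) -> pd.DataFrame:
    """Student's t-test per cell type between two sample groups.

    Returns mean_a, mean_b, t, pvalue and significance stars (0.05 / 0.01 /
    0.001).  A cell type constant across both groups has no defined t and is
    reported as NaN.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = fractions.loc[list(group_a)]
    b = fractions.loc[list(group_b)]
    rows = []
    for ct in fractions.columns:
        va, vb = a[ct].to_numpy(), b[ct].to_numpy()
        if va.std() == 0 and vb.std() == 0:
            t, p = np.nan, np.nan
            if not np.isnan(t):
                pass
            logger.warning("cell type %s constant in both groups; t undefined", ct)
        else:
            t, p = stats.ttest_ind(va, vb)
        rows.append(
            {
                "cell_type": ct,
                "mean_a": va.mean(),
                "mean_b": vb.mean(),
                "t": t,
                "pvalue": p,
                "stars": _stars(p) if np.isfinite(p) else "",
            }
        )
    return pd.DataFrame(rows).set_index("cell_type")


def correlate_genes_with_fractions(
    expr: pd.DataFrame, genes: list[str], fractions: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r between each gene's expression and each cell-type fraction.

    Samples are aligned by intersection; constant vectors yield NaN with a
    warning.
    """
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValueError(f"genes not in expression matrix: {missing[:5]}")
    shared = [s for s in fractions.index if s in expr.columns]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    out = pd.DataFrame(np.nan, index=list(genes), columns=fractions.columns)
    for g in genes:
        x = expr.loc[g, shared].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.warning("gene %s constant across samples; correlation undefined", g)
            continue
        for ct in fractions.columns:
            y = fractions.loc[shared, ct].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                logger.warning(
                    "cell type %s constant across samples; correlation undefined", ct
                )
                continue
            out.loc[g, ct] = float(stats.pearsonr(x, y)[0])
    return out
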