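"""Expression matrix IO, normalization and per-sample summaries.

The working representation throughout the package is a pandas DataFrame of
genes (uppercase symbols, unique) x samples, with an explicit normalization
tag carried in ``DataFrame.attrs["normalization"]`` (one of ``raw_counts``,
``CPM``, ``FPKM``, ``log2``).  Downstream statistics default to log2(CPM+1).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

VALID_CATEGORIES = {"NB", "IBT", "Fibro", "DCIS", "IDC"}
VALID_SUBTYPES = {"LuminalA", "LuminalB", "Her2", "TNBC", "none"}


def load_counts(count_path, metadata_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load a count TSV and its sample metadata, cleaning gene rows.

    Gene symbols are uppercased; duplicate symbols are collapsed keeping the
    row with the highest mean; genes with zero total count are dropped with a
    warning.  Sample ids must match between the two files.
    """
    expr = pd.read_csv(count_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)

    non_numeric = expr.columns[
        [not np.issubdtype(dt, np.number) for dt in expr.dtypes]
    ]
    if len(non_numeric):
        for col in non_numeric:
            bad = expr.index[pd.to_numeric(expr[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric cell in column {col!r}, gene(s) {list(bad[:5])}"
            )

    missing_in_expr = set(meta.index) - set(expr.columns)
    missing_in_meta = set(expr.columns) - set(meta.index)
    if missing_in_expr or missing_in_meta:
        raise ValueError(
            "sample mismatch between counts and metadata: "
            f"missing from counts {sorted(missing_in_expr)}, "
            f"missing from metadata {sorted(missing_in_meta)}"
        )
    expr = expr[meta.index]

    expr.index = expr.index.astype(str).str.upper()
    if expr.index.has_duplicates:
        means = expr.mean(axis=1)
        keep = (
            pd.DataFrame({"gene": expr.index, "mean": means.to_numpy()})
            .reset_index(drop=True)
            .groupby("gene")["mean"]
            .idxmax()
        )
        n_dropped = len(expr) - len(keep)
        expr = expr.iloc[sorted(keep.to_numpy())]
        logger.warning("collapsed %d duplicate gene symbol rows", n_dropped)

    zero = expr.sum(axis=1) == 0
    if zero.any():
        logger.warning("dropping %d genes with zero total count", int(zero.sum()))
        expr = expr.loc[~zero]

    bad_cat = set(meta["category"]) - VALID_CATEGORIES
    if bad_cat:
        raise ValueError(f"unknown categories in metadata: {sorted(bad_cat)}")
    expr.attrs["normalization"] = "raw_counts"
    return expr, meta


def normalize(
    expr: pd.DataFrame,
    method: str = "CPM",
    gene_lengths: dict[str, float] | pd.Series | None = None,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Library-size normalize counts to CPM or FPKM, optionally log2(x+1).

    CPM columns sum to 1e6 before the log transform.  FPKM divides by gene
    length in kilobases and requires a length for every gene.
    """
    method = method.upper()
    if method not in {"CPM", "FPKM"}:
        raise ValueError(f"unknown normalization method {method!r}")
    totals = expr.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        raise ValueError("cannot normalize a sample with zero total count")
    values = expr.to_numpy(dtype=float) / totals * 1e6
    if method == "FPKM":
        if gene_lengths is None:
            raise ValueError("FPKM normalization requires gene_lengths")
        lengths = pd.Series(gene_lengths)
        missing = expr.index.difference(lengths.index)
        if len(missing):
            raise ValueError(f"missing gene length for {list(missing[:5])}")
        kb = lengths.reindex(expr.index).to_numpy(dtype=float) / 1000.0
        values = values / kb[:, None]
    tag = method
    if log_transform:
        values = np.log2(values + 1.0)
        tag = "log2"
    out = pd.DataFrame(values, index=expr.index, columns=expr.columns)
    out.attrs["normalization"] = tag
    return out


def similarity_to_reference(
    expr: pd.DataFrame, reference_samples: list[str]
) -> pd.Series:
    """Pearson correlation of each sample with the mean reference profile.

    The reference profile is the per-gene mean over ``reference_samples``.
    A constant sample (or reference) vector has undefined correlation and is
    reported as NaN with a warning.
    """
    if not len(reference_samples):
        raise ValueError("reference sample set is empty")
    missing = set(reference_samples) - set(expr.columns)
    if missing:
        raise ValueError(f"reference samples not in matrix: {sorted(missing)}")
    ref = expr[list(reference_samples)].mean(axis=1).to_numpy()
    out = {}
    ref_const = np.ptp(ref) == 0
    for s in expr.columns:
        v = expr[s].to_numpy(dtype=float)
        if ref_const or np.ptp(v) == 0:
            logger.warning("constant vector for sample %s: correlation undefined", s)
            out[s] = np.nan
        else:
            out[s] = float(stats.pearsonr(v, ref)[0])
    return pd.Series(out, name="pcc_to_reference")


def compute_pca(
    expr: pd.DataFrame,
    n_top_variable_genes: int = 2000,
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered (unscaled) PCA of samples over the top-variance genes.

    Returns sample coordinates (samples x components) and the explained
    variance fractions, which are non-increasing and sum to at most 1.
    """
    if n_components > min(expr.shape):
        raise ValueError("n_components exceeds min(genes, samples)")
    variances = expr.var(axis=1)
    if n_top_variable_genes < len(expr):
        genes = variances.nlargest(n_top_variable_genes).index
    else:
        if n_top_variable_genes > len(expr):
            logger.warning(
                "requested %d variable genes but only %d available; using all",
                n_top_variable_genes,
                len(expr),
            )
        genes = expr.index
    x = expr.loc[genes].to_numpy(dtype=float).T  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(coords, index=expr.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


def classify_subtype(expr: pd.DataFrame, centroids: pd.DataFrame) -> pd.Series:
    """Nearest-centroid intrinsic subtype call by Spearman correlation.

    ``centroids`` is genes x subtype labels (e.g. a 50-gene intrinsic
    signature).  Each sample is assigned the label of the centroid with the
    highest Spearman correlation over shared genes; exact ties yield
    "unclassified".
    """
    shared = expr.index.intersection(centroids.index)
    if len(shared) == 0:
        raise ValueError("no genes shared between expression and centroids")
    if len(shared) < 10:
        raise ValueError(
            f"only {len(shared)} centroid genes present in expression; >= 10 required"
        )
    sub = expr.loc[shared]
    cent = centroids.loc[shared]
    labels = {}
    for s in sub.columns:
        rs = {
            lab: stats.spearmanr(sub[s], cent[lab]).statistic
            for lab in cent.columns
        }
        best = max(rs.values())
        winners = [lab for lab, r in rs.items() if r == best]
        labels[s] = winners[0] if len(winners) == 1 else "unclassified"
    return pd.Series(labels, name="subtype_call")
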