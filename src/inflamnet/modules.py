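"""k-means expression clusters and trend-based disease modules.

Differentially expressed genes are z-scored per gene and clustered with
Euclidean k-means (k = 13 by default).  Clusters whose per-category mean
z-profile is high in a named set of disease groups and low elsewhere are
united into named modules, e.g. IBT_Her2_TNBC (high in inflammation and
ER-negative tumors) and Her2_TNBC (high in ER-negative tumors only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

DEFAULT_K = 13


@dataclass
class ClusterSet:
    """Gene -> cluster assignment (ids 1..k) with per-cluster profiles."""

    assignments: pd.Series  # gene -> cluster id
    profiles: pd.DataFrame  # cluster x sample mean z
    inertia: float

    @property
    def k(self) -> int:
        return int(self.assignments.max()) if len(self.assignments) else 0

    def genes_in(self, cluster_id: int) -> list[str]:
        return list(self.assignments.index[self.assignments == cluster_id])


@dataclass
class ModuleDefinition:
    name: str
    clusters: list[int]
    genes: list[str]
    high_in: set[str] = field(default_factory=set)


def zscore_rows(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score; zero-variance rows are dropped with a warning."""
    values = expr.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    keep = sd.ravel() > 0
    if not keep.all():
        logger.warning(
            "excluding %d zero-variance genes before z-scoring", int((~keep).sum())
        )
    z = (values[keep] - mu[keep]) / sd[keep]
    return pd.DataFrame(z, index=expr.index[keep], columns=expr.columns)


def cluster_genes(
    expr: pd.DataFrame,
    genes: list[str] | None = None,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterSet:
    """Euclidean k-means over per-gene z-scored profiles, best of restarts.

    Returns contiguous cluster ids 1..k, per-cluster mean z profiles and the
    within-cluster sum of squares of the selected solution.
    """
    sub = expr.loc[genes] if genes is not None else expr
    missing = [g for g in (genes or []) if g not in expr.index]
    if missing:
        raise ValueError(f"genes not in expression matrix: {missing[:5]}")
    z = zscore_rows(sub)
    if k > len(z):
        raise ValueError(f"k={k} exceeds {len(z)} clusterable genes")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(z.to_numpy())
    assignments = pd.Series(labels + 1, index=z.index, name="cluster")
    profiles = z.groupby(assignments).mean()
    profiles.index.name = "cluster"
    return ClusterSet(assignments=assignments, profiles=profiles, inertia=km.inertia_)


def summarize_clusters(
    expr: pd.DataFrame, clusters: ClusterSet, samples: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster per-category mean z-score.

    The cluster value in a sample is the mean z of its member genes; the
    category value is the mean over that category's samples.  IDC samples are
    summarized per subtype (LuminalA/LuminalB/Her2/TNBC) so trend rules can
    address ER-negative subtypes directly.
    """
    z = zscore_rows(expr.loc[clusters.assignments.index])
    per_sample = z.groupby(clusters.assignments).mean()
    group = samples["category"].where(
        samples["subtype"] == "none", samples["subtype"]
    )
    per_cat = per_sample.T.groupby(group.reindex(per_sample.columns)).mean().T
    per_cat.index.name = "cluster"
    return per_cat


def assign_modules(
    category_z: pd.DataFrame,
    rules: list[tuple[str, set[str]]],
    tau_hi: float = 0.5,
    tau_lo: float = 0.0,
    clusters: ClusterSet | None = None,
    overrides: dict[int, str] | None = None,
) -> list[ModuleDefinition]:
    """Assign clusters to named modules by expression-trend rules.

    A cluster joins module M iff its category-mean z is >= tau_hi in every
    category of M's high_in set and <= tau_lo in every other category.
    Explicit cluster -> module overrides take precedence over the thresholds.
    A cluster matching two rules is an error (rules must be exclusive).
    """
    if not tau_hi > tau_lo:
        raise ValueError("tau_hi must exceed tau_lo")
    overrides = overrides or {}
    members: dict[str, list[int]] = {name: [] for name, _ in rules}
    for name in overrides.values():
        if name not in members:
            raise ValueError(f"override targets unknown module {name!r}")
    for cid in category_z.index:
        if cid in overrides:
            members[overrides[cid]].append(cid)
            continue
        matched = []
        row = category_z.loc[cid]
        for name, high_in in rules:
            hi = all(row.get(cat, -np.inf) >= tau_hi for cat in high_in)
            lo = all(
                row[cat] <= tau_lo for cat in category_z.columns if cat not in high_in
            )
            if hi and lo:
                matched.append(name)
        if len(matched) > 1:
            raise ValueError(
                f"cluster {cid} matches multiple module rules: {matched}"
            )
        if matched:
            members[matched[0]].append(cid)
    out = []
    for name, high_in in rules:
        cids = sorted(members[name])
        genes: list[str] = []
        if clusters is not None:
            for cid in cids:
                genes.extend(clusters.genes_in(cid))
        out.append(
            ModuleDefinition(name=name, clusters=cids, genes=genes, high_in=set(high_in))
        )
    return out


DEFAULT_MODULE_RULES: list[tuple[str, set[str]]] = [
    ("IBT_Her2_TNBC", {"IBT", "Her2", "TNBC"}),
    ("Her2_TNBC", {"Her2", "TNBC"}),
]
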