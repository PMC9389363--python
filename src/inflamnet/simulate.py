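"""Synthetic study generator.

Emulates a 46-sample five-category breast-tissue cohort (normal breast NB,
inflammatory breast tissue IBT, fibroadenoma Fibro, ductal carcinoma in situ
DCIS, invasive ductal carcinoma IDC with four receptor subtypes) together with
every downstream input the pipeline consumes: negative-binomial RNA-seq counts
with planted co-regulated gene modules, a STRING-style protein-interaction edge
list with planted intra- and cross-module edges, linear cell-type mixtures of a
signature matrix, and proportional-hazards survival times with known
coefficients.  All generators are pure functions of their arguments including
the seed, so every simulated dataset is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = ("NB", "IBT", "Fibro", "DCIS", "IDC")
IDC_SUBTYPES = ("LuminalA", "LuminalB", "Her2", "TNBC")

DEFAULT_CATEGORY_COUNTS = {"NB": 5, "IBT": 5, "Fibro": 5, "DCIS": 5}
DEFAULT_SUBTYPE_COUNTS = {"LuminalA": 5, "LuminalB": 11, "Her2": 5, "TNBC": 5}


class ConfigurationError(ValueError):
    """Raised when a generator is given an invalid configuration."""


@dataclass
class DesignConfig:
    """Cohort layout: how many samples per disease category and IDC subtype.

    Defaults mirror a 46-case design: five samples in each of the four
    non-invasive categories plus 26 invasive carcinomas split 5/11/5/5 across
    LuminalA / LuminalB / Her2 / TNBC.
    """

    counts_per_category: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_COUNTS)
    )
    idc_subtype_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_COUNTS)
    )
    seed: int = 0

    def validate(self) -> None:
        for name, counts, allowed in (
            ("counts_per_category", self.counts_per_category, CATEGORIES),
            ("idc_subtype_counts", self.idc_subtype_counts, IDC_SUBTYPES),
        ):
            for key, n in counts.items():
                if key not in allowed:
                    raise ConfigurationError(f"{name}: unknown label {key!r}")
                if not isinstance(n, (int, np.integer)) or n < 0:
                    raise ConfigurationError(
                        f"{name}[{key!r}] must be a non-negative integer, got {n!r}"
                    )
        if "IDC" in self.counts_per_category:
            raise ConfigurationError(
                "IDC sample count is defined by idc_subtype_counts, not "
                "counts_per_category"
            )

    @property
    def total(self) -> int:
        return sum(self.counts_per_category.values()) + sum(
            self.idc_subtype_counts.values()
        )


@dataclass
class PlantedModuleSpec:
    """A block of co-regulated genes up-regulated in a set of groups.

    ``up_in`` may mix category labels (IBT, DCIS...) and IDC subtype labels
    (Her2, TNBC...); a sample is affected if either its category or its
    subtype is in the set.  ``log2_effect`` is the planted log2 fold change;
    ``correlation`` in [0, 1] scales a shared per-sample latent factor that
    induces within-module co-expression beyond the group effect.
    """

    module_name: str
    gene_count: int
    up_in: frozenset[str] | set[str]
    log2_effect: float = 2.0
    correlation: float = 0.5

    def validate(self) -> None:
        if self.gene_count <= 0:
            raise ConfigurationError("gene_count must be positive")
        if not self.up_in:
            raise ConfigurationError("up_in must be non-empty")
        if not np.isfinite(self.log2_effect):
            raise ConfigurationError("log2_effect must be finite")
        if not 0.0 <= self.correlation <= 1.0:
            raise ConfigurationError("correlation must be in [0, 1]")
        unknown = set(self.up_in) - set(CATEGORIES) - set(IDC_SUBTYPES)
        if unknown:
            raise ConfigurationError(f"up_in contains unknown labels {unknown}")


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset, for recovery checks."""

    gene_modules: dict[str, str] = field(default_factory=dict)
    de_status: pd.DataFrame | None = None
    cross_edges: list[tuple[str, str]] = field(default_factory=list)
    intra_edges: list[tuple[str, str]] = field(default_factory=list)
    proportions: pd.DataFrame | None = None
    betas: np.ndarray | None = None


def generate_study_design(config: DesignConfig | None = None) -> pd.DataFrame:
    """Build the sample table for a cohort design.

    Returns a DataFrame indexed by sample id with ``category`` and ``subtype``
    columns; subtype is "none" except for IDC samples.
    """
    if config is None:
        config = DesignConfig()
    config.validate()
    rows = []
    i = 1
    for cat in CATEGORIES[:4]:
        for _ in range(config.counts_per_category.get(cat, 0)):
            rows.append((f"S{i:03d}", cat, "none"))
            i += 1
    for sub in IDC_SUBTYPES:
        for _ in range(config.idc_subtype_counts.get(sub, 0)):
            rows.append((f"S{i:03d}", "IDC", sub))
            i += 1
    table = pd.DataFrame(rows, columns=["sample", "category", "subtype"])
    return table.set_index("sample")


def _affected_mask(design: pd.DataFrame, up_in: set[str]) -> np.ndarray:
    up = set(up_in)
    return (design["category"].isin(up) | design["subtype"].isin(up)).to_numpy()


def generate_expression(
    design: pd.DataFrame,
    modules: list[PlantedModuleSpec] | None = None,
    background_genes: int = 2000,
    dispersion: float = 0.1,
    seed: int = 0,
    base_mean_log_sd: float = 1.5,
    library_size_log_sd: float = 0.2,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a negative-binomial count matrix with planted modules.

    Counts for gene g, sample s are NB with mean
    ``mu_g * L_s * 2^(log2_effect) [if s affected] * exp(c * f_s)`` where L_s
    is a log-normal library-size factor and f_s a module-shared latent factor
    scaled by the module's ``correlation``.  Variance is ``mu + dispersion *
    mu^2``.  Gene names: planted genes ``<MODULE>_G<i>``, background ``BG<i>``.
    """
    modules = modules or []
    for m in modules:
        m.validate()
    if background_genes < 0:
        raise ConfigurationError("background_genes must be >= 0")
    if dispersion <= 0:
        raise ConfigurationError("dispersion must be > 0")
    n_planted = sum(m.gene_count for m in modules)
    rng = np.random.default_rng(seed)
    n_samples = len(design)

    gene_names: list[str] = []
    gene_modules: dict[str, str] = {}
    for m in modules:
        for j in range(m.gene_count):
            name = f"{m.module_name.upper()}_G{j + 1}"
            gene_names.append(name)
            gene_modules[name] = m.module_name
    gene_names.extend(f"BG{j + 1}" for j in range(background_genes))
    n_genes = n_planted + background_genes
    if n_genes == 0:
        raise ConfigurationError("no genes to simulate")

    base_mean = np.exp(rng.normal(np.log(50.0), base_mean_log_sd, size=n_genes))
    lib = np.exp(rng.normal(0.0, library_size_log_sd, size=n_samples))

    mu = np.outer(base_mean, lib)  # genes x samples
    de_rows = []
    row = 0
    for m in modules:
        mask = _affected_mask(design, set(m.up_in))
        fold = 2.0 ** m.log2_effect
        mu[row : row + m.gene_count, mask] *= fold
        if m.correlation > 0:
            latent = rng.normal(0.0, 0.25, size=n_samples)
            mu[row : row + m.gene_count, :] *= np.exp(m.correlation * latent)
        for j in range(m.gene_count):
            de_rows.append(
                {
                    "gene": gene_names[row + j],
                    "module": m.module_name,
                    "up_in": ",".join(sorted(m.up_in)),
                    "log2_effect": m.log2_effect,
                }
            )
        row += m.gene_count

    # NB(mean mu, var mu + a mu^2): shape r = 1/a, p = r / (r + mu)
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    expr = pd.DataFrame(counts, index=gene_names, columns=design.index)
    truth = GroundTruth(
        gene_modules=gene_modules,
        de_status=pd.DataFrame(de_rows) if de_rows else None,
    )
    return expr, truth


def generate_ppi(
    genes: list[str],
    modules: dict[str, str],
    p_intra: float = 0.3,
    p_cross: float = 0.05,
    confidence_range: tuple[int, int] = (700, 1000),
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a STRING-style edge list over module genes.

    Each unordered pair of genes that both carry a module label receives an
    edge with probability ``p_intra`` (same module) or ``p_cross`` (different
    modules); genes without a module label stay isolated.  Confidence scores
    are integers uniform over ``confidence_range`` (inclusive).
    """
    for p, name in ((p_intra, "p_intra"), (p_cross, "p_cross")):
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1]")
    lo, hi = confidence_range
    if not (0 <= lo <= hi <= 1000):
        raise ConfigurationError("confidence_range must be within [0, 1000]")
    rng = np.random.default_rng(seed)
    rows = []
    cross: list[tuple[str, str]] = []
    intra: list[tuple[str, str]] = []
    labelled = [g for g in genes if g in modules]
    for i, a in enumerate(labelled):
        for b in labelled[i + 1 :]:
            same = modules[a] == modules[b]
            p = p_intra if same else p_cross
            if rng.random() < p:
                conf = int(rng.integers(lo, hi + 1))
                rows.append((a, b, conf))
                (intra if same else cross).append(tuple(sorted((a, b))))
    table = pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])
    return table, GroundTruth(
        gene_modules=dict(modules), cross_edges=cross, intra_edges=intra
    )


def generate_mixture(
    signature: pd.DataFrame,
    proportions: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Mix signature-matrix columns linearly into per-sample expression.

    ``signature`` is genes x cell types (linear scale), ``proportions`` is
    samples x cell types; each row must sum to 1 within 1e-9.  Gaussian noise
    of sd ``noise_sd`` is added and the result truncated at zero.
    """
    missing = set(proportions.columns) - set(signature.columns)
    if missing:
        raise ConfigurationError(f"proportions name unknown cell types: {missing}")
    p = proportions[signature.columns].to_numpy(dtype=float)
    if (p < 0).any():
        raise ConfigurationError("proportions must be non-negative")
    sums = p.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-9, rtol=0):
        bad = proportions.index[np.abs(sums - 1.0) > 1e-9].tolist()
        raise ConfigurationError(f"proportion rows do not sum to 1: {bad}")
    rng = np.random.default_rng(seed)
    mix = signature.to_numpy(dtype=float) @ p.T
    if noise_sd > 0:
        mix = mix + rng.normal(0.0, noise_sd, size=mix.shape)
    return pd.DataFrame(
        np.clip(mix, 0.0, None), index=signature.index, columns=proportions.index
    )


def generate_survival(
    n: int,
    covariates: np.ndarray | pd.DataFrame,
    betas: np.ndarray,
    baseline_rate: float = 0.001,
    censor_rate: float = 0.0005,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate event times under a proportional-hazards model.

    Event times are exponential with rate ``baseline_rate * exp(x @ betas)``;
    censoring times are independent exponential with rate ``censor_rate``
    (``censor_rate == 0`` means no censoring).  Returns a table with columns
    ``time`` (observed, > 0) and ``event`` (1 if the event was observed).
    """
    if n <= 0:
        raise ConfigurationError("n must be positive")
    x = np.asarray(
        covariates.to_numpy() if isinstance(covariates, pd.DataFrame) else covariates,
        dtype=float,
    )
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != n:
        raise ConfigurationError(f"covariates have {x.shape[0]} rows, expected {n}")
    betas = np.asarray(betas, dtype=float).ravel()
    if betas.size != x.shape[1]:
        raise ConfigurationError("betas length must equal covariate columns")
    if baseline_rate <= 0 or censor_rate < 0:
        raise ConfigurationError("baseline_rate must be > 0 and censor_rate >= 0")
    rng = np.random.default_rng(seed)
    rate = baseline_rate * np.exp(x @ betas)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    idx = (
        covariates.index
        if isinstance(covariates, pd.DataFrame)
        else [f"P{i + 1:04d}" for i in range(n)]
    )
    return pd.DataFrame({"time": time, "event": event}, index=idx)


def default_signature(
    n_genes: int = 60, cell_types: list[str] | None = None, seed: int = 0
) -> pd.DataFrame:
    """A synthetic signature matrix with one marker block per cell type.

    Each cell type gets a dedicated block of high-expression marker genes on a
    shared low background, giving a well-conditioned deconvolution basis.
    """
    if cell_types is None:
        cell_types = [f"Cell{j + 1}" for j in range(6)]
    rng = np.random.default_rng(seed)
    k = len(cell_types)
    base = rng.uniform(1.0, 10.0, size=(n_genes, k))
    block = n_genes // k
    for j in range(k):
        base[j * block : (j + 1) * block, j] += rng.uniform(80.0, 120.0, size=block)
    genes = [f"SIG{i + 1}" for i in range(n_genes)]
    return pd.DataFrame(base, index=genes, columns=cell_types)


def write_counts_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def write_metadata_tsv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index_label="sample")


def write_edges_tsv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def write_signature_tsv(signature: pd.DataFrame, path) -> None:
    signature.to_csv(path, sep="\t", index_label="gene")


def write_survival_tsv(surv: pd.DataFrame, path) -> None:
    surv.to_csv(path, sep="\t", index_label="sample")
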