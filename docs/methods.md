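# Methods

This note documents the models, defaults and numerical choices behind
`inflamnet`, and what the synthetic benchmarks do and do not show.

## Study design and data model

The unit of analysis is a bulk RNA-seq cohort over five tissue categories —
normal breast (NB), inflammatory breast tissue (IBT), fibroadenoma (Fibro),
ductal carcinoma in situ (DCIS), invasive ductal carcinoma (IDC) — with IDC
subdivided into LuminalA, LuminalB, Her2 and TNBC by receptor status. The
default simulated design is 5/5/5/5 non-invasive samples plus 26 IDC
(5 LuminalA, 11 LuminalB, 5 Her2, 5 TNBC), 46 samples in total. "ER⁻"
always means the union of Her2 and TNBC samples.

Counts are modelled as negative binomial with variance μ + αμ² (dispersion
α, default 0.1 — mid-range for bulk tissue), gene base means log-normal
around 50 (log-sd 1.5), and log-normal library-size factors (log-sd 0.2).
A planted module multiplies the means of its genes by 2^(log₂ effect) in
samples whose category or subtype is in its `up_in` set, and shares a
per-sample latent factor (scaled by the module's `correlation` parameter,
default 0.5) that induces co-expression beyond the group effect. These
defaults describe a generic bulk experiment; they are not calibrated to any
particular deposited dataset.

The working scale for all downstream statistics is log₂(CPM+1). FPKM is
available when gene lengths are supplied, but CPM is the length-free
default. Gene identity is the uppercase symbol; all cross-file joins use
symbols, duplicate symbols collapse to the row with the highest mean, and
zero-count genes are dropped at load time.

## Differential expression

Per gene, a Welch t-test on log₂ values between a disease group and NB;
log₂FC is the difference of group means; Benjamini–Hochberg adjustment over
all tested genes. Calls use the strict thresholds |FC| > 1.5 and adjusted
p < 0.05. Genes with zero variance in both groups are reported as `ns` with
p = 1. The Welch test was chosen over a count-model fit so the stage is
fully owned, transparent and fast; on synthetic data its strong-effect calls
agree with an independent negative-binomial GLM (checked in the test suite),
but fold changes on real data will differ from shrinkage-based estimators.

Under the default 46-sample design the 5-vs-5 IBT contrast has limited
power (≈0.85–0.9 at a 4-fold effect after BH); module detection therefore
uses the union of DE genes across all four contrasts, which recovers
planted modules essentially completely.

## Module detection

DE-union genes are z-scored per gene and clustered with Euclidean k-means,
best of 10 restarts, k = 13 by default. k is a configuration knob, not
selected by any criterion. Cluster trends are summarized as per-category
mean z (IDC broken out by subtype), and a cluster joins a named module when
its mean z is ≥ τ_hi (default 0.5) in every category of the module's
`high_in` set and ≤ τ_lo (default 0.0) everywhere else. The threshold rule
is a deterministic surrogate for choosing trend clusters by inspection;
explicit cluster→module overrides are honored for exact manual control, and
a cluster matching two rules is an error so module gene sets never overlap.

## NP network and interface genes

Interactions are read from STRING-style TSVs (protein1, protein2,
combined_score) or unscored pair lists; unscored sources are assigned
confidence 1000 so curated interactomes pass the confidence filter. Edges
need confidence > 900 (strict), are deduplicated to the maximum score, and
self-loops are dropped. Restricted to the two modules' genes, each edge's
Pearson correlation is computed over a configurable sample set (default:
all samples; the demo uses NB ∪ IBT ∪ Her2 ∪ TNBC, the categories spanned
by the two modules) and kept when |r| > 0.22 (strict), with sign and
intra/cross scope annotations. Interface genes are module genes with at
least one cross-module edge, reported with cross-edge counts, sorted by
count then name. The same correlation filter applies to intra- and
cross-module edges. Constant-expression genes cannot carry a correlation
and their edges are dropped with a warning.

## Enrichment and pathway activity

Over-representation is the one-sided hypergeometric upper tail
P[X ≥ overlap] per gene set, BH-adjusted across sets; the default universe
is the measured genes. Set-overlap association uses a χ² test with
continuity correction on the 2×2 membership table, replaced by a one-sided
Fisher exact test (over-overlap alternative) whenever an expected cell is
≤ 5; odds ratios with a zero margin are capped at 10⁶.

Per-sample pathway activity is an ssGSEA-style statistic: genes are ranked
within the sample, a running sum steps up by rank^0.25 (normalized over
members) at member genes and down by 1/(N−|S|) otherwise, and the score is
the maximum-deviation value. It depends on ranks only, so any monotone
transform of a sample leaves scores unchanged. Sets with fewer than 5
measured genes are skipped. Scores are comparable across samples sharing a
gene universe but are not calibrated to any external enrichment tool.

## Deconvolution

Cell fractions solve a non-negative least squares problem per sample
against the signature matrix restricted to shared genes (≥ 50% of signature
genes required), then renormalize to sum to one; reconstruction RMSE is
reported. Input must be linear-scale; matrices whose maximum is below 50
are rejected as likely log-transformed. NNLS was chosen over support-vector
regression as a fully specified convex solver with exact noiseless
recovery; fractions on real data will differ from SVR-based estimates.
Group comparisons are per-cell-type Student t-tests with 0.05/0.01/0.001
significance stars.

## Survival and risk scoring

The Cox engine maximizes the Breslow partial likelihood by Newton's method
with step halving, converging to gradient norm < 1e-8 within 100 iterations;
a singular or non-convergent fit falls back to a ridge penalty of 1e-6, and
coefficient blow-up (>50) is flagged as likely monotone likelihood.
Covariates are standardized before fitting so hazard ratios are per SD.
Screening keeps genes with HR > 1 and Wald p < 0.05 (strict), sorted by p.
The multivariate risk score is the linear predictor; the high-risk group is
score > median with ties assigned low, deterministically. Kaplan–Meier
curves, the log-rank test and Harrell's concordance index come from
lifelines. Simulated survival is exponential with rate
baseline·exp(xβ) and independent exponential censoring; censor rate 0 means
no censoring.

## What the synthetic benchmarks show

Passing tests demonstrate: exact agreement of interface extraction, BH and
ORA with brute-force definitions; exact noiseless and sub-0.05-error noisy
deconvolution recovery; Cox estimates matching a grid-maximized Breslow
likelihood and recovering planted coefficients within 3 SE; ARI = 1 cluster
recovery of well-separated profiles; and type-I error control of the DE
stage on nulls. They do not demonstrate robustness to batch effects,
probe-level artifacts, mis-annotated samples, signature mismatch between
tissue and reference, or violations of proportional hazards — none of which
the generator emulates. Problem sizes in the tests and the acceptance
script (≈2,000-gene universes, 46–1,000 samples, 100-instance property
sweeps) are desk-scale choices that keep the full suite under a minute
while exercising every code path.

## Known limitations

- The DE stage is a two-group location test; it does not model counts
  directly and has reduced power in 5-vs-5 contrasts at shallow depth.
- Module assignment depends on τ_hi/τ_lo; clusters with mixed trends stay
  unassigned rather than being forced into a module.
- The correlation sample set for the NP network is a genuine free choice;
  results can change with it, so it is configuration, not inference.
- Pathway scores and deconvolution fractions are internally consistent but
  not numerically comparable to GSVA or CIBERSORT outputs.
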