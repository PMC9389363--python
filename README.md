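# inflamnet

Analysis pipeline for the inflammation–cancer interface in bulk breast
transcriptomes.

Chronic inflammation is a suspected precursor of estrogen-receptor-negative
(ER⁻) breast cancer. Given a gene × sample count matrix over a cohort of
normal breast (NB), inflammatory breast tissue (IBT), fibroadenoma (Fibro),
ductal carcinoma in situ (DCIS) and invasive ductal carcinoma (IDC, with
LuminalA / LuminalB / Her2 / TNBC subtypes), `inflamnet` identifies the genes
that sit at the molecular interface between the inflammation and cancer
expression programs, and turns them into a prognostic risk score. It is
aimed at computational biologists analyzing bulk RNA-seq of inflammatory and
tumor tissue.

## Method

1. **Differential expression.** Each disease group is contrasted against NB
   on log₂(CPM+1) with a per-gene Welch t-test and Benjamini–Hochberg
   correction; a gene is called when |FC| > 1.5 and adjusted *p* < 0.05
   (both strict). The four default contrasts are IBT, ER⁻ (= Her2 ∪ TNBC),
   Her2 and TNBC versus NB.
2. **Expression modules.** The union of DE genes is z-scored per gene and
   clustered with Euclidean k-means (k = 13 by default). Clusters whose
   per-category mean z is ≥ τ_hi in a named group set and ≤ τ_lo elsewhere
   form disease modules: `IBT_Her2_TNBC` (high in inflammation *and* ER⁻
   tumors) and `Her2_TNBC` (high in ER⁻ tumors only).
3. **NP network and interface genes.** Protein–protein interactions with
   combined score > 900 are restricted to the two modules' genes; an edge is
   kept when the expression Pearson correlation satisfies |r| > 0.22
   (strict), annotated with its sign (the "negative-positive" network) and
   scope (intra/cross-module). Genes with at least one **cross-module** edge
   are the *interface genes* — the inflammation–cancer interface.
4. **Interpretation layers.** Hypergeometric over-representation of the
   interface genes against GMT gene sets; χ²/Fisher set-overlap tests;
   ssGSEA-style per-sample pathway activity; NNLS deconvolution of cell-type
   fractions from a signature matrix (LM22-format immune, 7-subtype
   erythroid) with per-group t-tests.
5. **Risk score.** Univariate Cox screening of interface genes (Breslow
   ties, Newton optimization) keeps genes with HR > 1 and *p* < 0.05; a
   multivariate Cox fit defines the risk score Σ β_g·x_g, samples are split
   at the median score and compared by log-rank test and Kaplan–Meier
   curves, with Harrell's concordance index reported.

A synthetic-data module simulates every input with known ground truth: the
46-sample five-category cohort, negative-binomial counts with planted
up-regulated modules, STRING-style PPI edges with planted cross-module
structure, linear signature mixtures, and proportional-hazards survival
times.

## Worked example

Run the whole pipeline on a simulated study (everything is generated from
the seed):

```bash
inflamnet run --demo --seed 0 --outdir demo_out
```

This prints a summary (abridged):

```json
{
 "stages": {
  "simulate":   {"n_samples": 46, "n_idc": 26, "n_genes": 2150},
  "de":         {"contrasts": {"IBT_vs_NB": 20, "ERneg_vs_NB": 111,
                 "Her2_vs_NB": 86, "TNBC_vs_NB": 52}, "de_gene_union": 117},
  "modules":    {"k": 13, "IBT_Her2_TNBC": 53, "Her2_TNBC": 40},
  "np_network": {"nodes": 93, "edges": 915, "cross_edges": 269,
                 "interface_IBT_Her2_TNBC": 53, "interface_Her2_TNBC": 40},
  "deconvolution": {"n_cell_types": 6, "mean_abs_error_vs_truth": 0.0024},
  "risk":       {"n_risk_genes": 3, "concordance": 0.79,
                 "logrank_p": 1.97e-32}
 }
}
```

Reading it: the simulated cohort reproduces the 46-sample design (26 IDC);
117 genes are differentially expressed in at least one contrast; k-means
finds the two planted disease modules (53 and 40 genes); after confidence
and correlation filtering the NP network keeps 915 interactions of which 269
cross modules, yielding 53 and 40 interface genes; deconvolution recovers
the planted cell fractions to 0.002 mean absolute error; the Cox screen
selects 3 risk genes whose median-split risk score separates survival
(log-rank p ≈ 2e-32) with concordance 0.79.

Every stage is also available as a subcommand on real data
(`simulate`, `normalize`, `de`, `np-network`, `enrich`, `deconvolve`,
`pathway`, `risk`, `validate-config`), and as plain library functions under
`inflamnet.*`.

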