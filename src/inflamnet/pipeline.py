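"""End-to-end orchestration: normalize -> DE -> clusters -> modules ->
NP network -> interface genes -> enrichment -> deconvolution -> pathway
scores -> risk model, driven by one YAML config, with every intermediate
artifact and a machine-readable summary written to a run directory.

When no input paths are configured the pipeline runs in demo mode: it
simulates the full study (cohort design, counts with planted modules, PPI
edges, signature mixtures, survival times) and analyzes the simulation, so a
complete run needs nothing but a seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import deconvolution as deconv_mod
from . import enrichment as enr_mod
from . import expression as expr_mod
from . import modules as mod_mod
from . import network as net_mod
from . import simulate as sim_mod
from . import survival as surv_mod

logger = logging.getLogger(__name__)

ALL_STAGES = [
    "simulate",
    "normalize",
    "de",
    "modules",
    "np_network",
    "enrichment",
    "deconvolution",
    "pathway",
    "risk",
]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(ALL_STAGES),
    "inputs": {
        "counts": None,
        "metadata": None,
        "interactions": [],
        "gmt": None,
        "signature": None,
        "survival": None,
    },
    "thresholds": {
        "fc": 1.5,
        "padj": 0.05,
        "k": 13,
        "r_threshold": 0.22,
        "confidence_threshold": 900,
        "tau_hi": 0.5,
        "tau_lo": 0.0,
        "cox_p": 0.05,
    },
    "simulate": {
        "background_genes": 2000,
        "dispersion": 0.1,
        "module_gene_count": 60,
        "log2_effect": 2.0,
        "n_survival": 300,
    },
}

_RANGES = {
    "fc": (1.0, 100.0),
    "padj": (0.0, 1.0),
    "k": (1, 1000),
    "r_threshold": (0.0, 1.0),
    "confidence_threshold": (0, 1000),
    "cox_p": (0.0, 1.0),
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        config = _merge(config, user)
    if overrides:
        config = _merge(config, overrides)
    return config


def validate_config(config: dict) -> list[str]:
    """Schema and range checks; returns a list of problems (empty = valid)."""
    problems = []
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        problems.append(f"unknown config keys: {sorted(unknown)}")
    for section in ("inputs", "thresholds", "simulate"):
        extra = set(config.get(section, {})) - set(DEFAULT_CONFIG[section])
        if extra:
            problems.append(f"unknown keys in {section}: {sorted(extra)}")
    thresholds = config.get("thresholds", {})
    for key, (lo, hi) in _RANGES.items():
        val = thresholds.get(key, DEFAULT_CONFIG["thresholds"][key])
        if not isinstance(val, (int, float)) or not lo <= val <= hi:
            problems.append(f"thresholds.{key}={val!r} outside [{lo}, {hi}]")
    if thresholds.get("k", 13) < 1:
        problems.append("thresholds.k must be >= 1")
    tau_hi = thresholds.get("tau_hi", 0.5)
    tau_lo = thresholds.get("tau_lo", 0.0)
    if not tau_hi > tau_lo:
        problems.append("thresholds.tau_hi must exceed tau_lo")
    stages = config.get("stages", ALL_STAGES)
    bad = set(stages) - set(ALL_STAGES)
    if bad:
        problems.append(f"unknown stages: {sorted(bad)}")
    for key, val in config.get("inputs", {}).items():
        if key == "interactions":
            for p in val or []:
                if not Path(p).exists():
                    problems.append(f"inputs.interactions path missing: {p}")
        elif val is not None and not Path(val).exists():
            problems.append(f"inputs.{key} path missing: {val}")
    return problems


DEMO_MODULES = [
    sim_mod.PlantedModuleSpec(
        "IBT_HER2_TNBC", 60, {"IBT", "Her2", "TNBC"}, log2_effect=2.0
    ),
    sim_mod.PlantedModuleSpec("HER2_TNBC", 60, {"Her2", "TNBC"}, log2_effect=2.0),
    sim_mod.PlantedModuleSpec("DCIS", 40, {"DCIS"}, log2_effect=2.0),
]


def _simulate_inputs(config: dict, outdir: Path) -> dict:
    seed = int(config["seed"])
    sim = config["simulate"]
    design = sim_mod.generate_study_design(sim_mod.DesignConfig(seed=seed))
    planted = [
        sim_mod.PlantedModuleSpec(
            "IBT_HER2_TNBC",
            sim["module_gene_count"],
            {"IBT", "Her2", "TNBC"},
            log2_effect=sim["log2_effect"],
        ),
        sim_mod.PlantedModuleSpec(
            "HER2_TNBC",
            sim["module_gene_count"],
            {"Her2", "TNBC"},
            log2_effect=sim["log2_effect"],
        ),
        sim_mod.PlantedModuleSpec(
            "DCIS",
            max(sim["module_gene_count"] // 2, 2),
            {"DCIS"},
            log2_effect=sim["log2_effect"],
        ),
    ]
    counts, truth = sim_mod.generate_expression(
        design,
        planted,
        background_genes=sim["background_genes"],
        dispersion=sim["dispersion"],
        seed=seed,
    )
    ppi, ppi_truth = sim_mod.generate_ppi(
        list(counts.index),
        truth.gene_modules,
        p_intra=0.3,
        p_cross=0.15,
        confidence_range=(901, 1000),
        seed=seed + 1,
    )
    signature = sim_mod.default_signature(seed=seed + 2)
    rng = np.random.default_rng(seed + 3)
    props = rng.dirichlet(np.ones(signature.shape[1]), size=len(design))
    proportions = pd.DataFrame(
        props, index=design.index, columns=signature.columns
    )
    mixture = sim_mod.generate_mixture(
        signature, proportions, noise_sd=1.0, seed=seed + 4
    )
    gene_sets = {
        "PLANTED_IBT_HER2_TNBC": [
            g for g, m in truth.gene_modules.items() if m == "IBT_HER2_TNBC"
        ],
        "PLANTED_HER2_TNBC": [
            g for g, m in truth.gene_modules.items() if m == "HER2_TNBC"
        ],
        "BACKGROUND_SLICE": [f"BG{i + 1}" for i in range(50)],
    }
    sim_mod.write_counts_tsv(counts, outdir / "counts.tsv")
    sim_mod.write_metadata_tsv(design, outdir / "metadata.tsv")
    sim_mod.write_edges_tsv(ppi, outdir / "interactions.tsv")
    sim_mod.write_gmt(gene_sets, outdir / "gene_sets.gmt")
    sim_mod.write_signature_tsv(signature, outdir / "signature.tsv")
    return {
        "design": design,
        "counts": counts,
        "truth": truth,
        "ppi_truth": ppi_truth,
        "interactions_path": outdir / "interactions.tsv",
        "signature": signature,
        "mixture": mixture,
        "proportions": proportions,
        "gene_sets": gene_sets,
    }


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the configured stages, writing artifacts and a summary JSON.

    Returns the summary dict.  Any stage failure raises with the stage name;
    artifacts of completed stages are left in place.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config["stages"]
    thresholds = config["thresholds"]
    seed = int(config["seed"])
    summary: dict = {"seed": seed, "thresholds": dict(thresholds), "stages": {}}

    state: dict = {}
    current = "setup"
    try:
        if "simulate" in stages or config["inputs"]["counts"] is None:
            current = "simulate"
            state.update(_simulate_inputs(config, outdir))
            counts, design = state["counts"], state["design"]
            counts.attrs["normalization"] = "raw_counts"
            summary["stages"]["simulate"] = {
                "n_samples": int(len(design)),
                "n_genes": int(len(counts)),
                "n_idc": int((design["category"] == "IDC").sum()),
            }
        else:
            current = "load"
            counts, design = expr_mod.load_counts(
                config["inputs"]["counts"], config["inputs"]["metadata"]
            )
            state.update({"counts": counts, "design": design})

        current = "normalize"
        logcpm = expr_mod.normalize(counts, method="CPM", log_transform=True)
        state["logcpm"] = logcpm
        logcpm.round(4).to_csv(outdir / "log2_cpm.tsv", sep="\t")
        if "normalize" in stages:
            summary["stages"]["normalize"] = {"tag": logcpm.attrs["normalization"]}

        if "de" in stages:
            current = "de"
            results = de_mod.run_contrasts(logcpm, design)
            for name, res in results.items():
                res.round(6).to_csv(outdir / f"de_{name}.tsv", sep="\t")
            de_genes = de_mod.de_gene_union(results)
            state["de_results"], state["de_genes"] = results, de_genes
            summary["stages"]["de"] = {
                "contrasts": {n: int((r["call"] != "ns").sum()) for n, r in results.items()},
                "de_gene_union": len(de_genes),
            }

        if "modules" in stages:
            current = "modules"
            clusters = mod_mod.cluster_genes(
                logcpm,
                state["de_genes"],
                k=int(thresholds["k"]),
                seed=seed,
            )
            category_z = mod_mod.summarize_clusters(logcpm, clusters, design)
            module_defs = mod_mod.assign_modules(
                category_z,
                mod_mod.DEFAULT_MODULE_RULES,
                tau_hi=thresholds["tau_hi"],
                tau_lo=thresholds["tau_lo"],
                clusters=clusters,
            )
            clusters.assignments.to_csv(outdir / "clusters.tsv", sep="\t")
            category_z.round(4).to_csv(outdir / "cluster_category_z.tsv", sep="\t")
            with open(outdir / "modules.yaml", "w") as fh:
                yaml.safe_dump(
                    {
                        m.name: {
                            "clusters": m.clusters,
                            "high_in": sorted(m.high_in),
                            "n_genes": len(m.genes),
                        }
                        for m in module_defs
                    },
                    fh,
                )
            state["clusters"], state["module_defs"] = clusters, module_defs
            summary["stages"]["modules"] = {
                "k": clusters.k,
                **{m.name: len(m.genes) for m in module_defs},
            }

        if "np_network" in stages:
            current = "np_network"
            paths = config["inputs"]["interactions"] or [state["interactions_path"]]
            interactions = net_mod.load_interactions(
                paths, confidence_threshold=int(thresholds["confidence_threshold"])
            )
            mod_a, mod_b = state["module_defs"][0], state["module_defs"][1]
            corr_samples = list(
                design.index[
                    design["category"].isin(["NB", "IBT"])
                    | design["subtype"].isin(["Her2", "TNBC"])
                ]
            )
            net = net_mod.build_np_network(
                interactions,
                mod_a,
                mod_b,
                state["logcpm"],
                correlation_samples=corr_samples,
                r_threshold=float(thresholds["r_threshold"]),
            )
            iface_a, iface_b = net_mod.extract_interface_genes(net)
            net_mod.network_to_edge_table(net).to_csv(
                outdir / "np_network_edges.tsv", sep="\t", index=False
            )
            iface_a.to_csv(outdir / f"interface_{mod_a.name}.tsv", sep="\t", index=False)
            iface_b.to_csv(outdir / f"interface_{mod_b.name}.tsv", sep="\t", index=False)
            state.update({"network": net, "iface_a": iface_a, "iface_b": iface_b})
            summary["stages"]["np_network"] = {
                "nodes": net.number_of_nodes(),
                "edges": net.number_of_edges(),
                "cross_edges": sum(
                    1 for *_, d in net.edges(data=True) if d["scope"] == "cross"
                ),
                f"interface_{mod_a.name}": len(iface_a),
                f"interface_{mod_b.name}": len(iface_b),
            }

        if "enrichment" in stages:
            current = "enrichment"
            if config["inputs"]["gmt"]:
                collection = enr_mod.read_gmt(config["inputs"]["gmt"])
            else:
                collection = state["gene_sets"]
            universe = set(state["logcpm"].index)
            enr = enr_mod.ora(set(state["iface_a"]["gene"]), collection, universe)
            enr.to_csv(outdir / "enrichment_interface_a.tsv", sep="\t", index=False)
            state["enrichment"] = enr
            top = enr.iloc[0] if len(enr) else None
            summary["stages"]["enrichment"] = {
                "n_terms": int(len(enr)),
                "top_term": None if top is None else str(top["term"]),
                "top_padj": None if top is None else float(top["padj"]),
            }

        if "deconvolution" in stages:
            current = "deconvolution"
            signature = (
                deconv_mod.read_signature(config["inputs"]["signature"])
                if config["inputs"]["signature"]
                else state["signature"]
            )
            mixture = state.get("mixture", counts)
            fractions, rmse = deconv_mod.estimate_fractions(mixture, signature)
            fractions.round(6).to_csv(outdir / "cell_fractions.tsv", sep="\t")
            state["fractions"] = fractions
            entry = {
                "n_cell_types": int(fractions.shape[1]),
                "mean_rmse": float(rmse.mean()),
            }
            if "proportions" in state:
                err = (
                    (fractions - state["proportions"][fractions.columns])
                    .abs()
                    .to_numpy()
                    .mean()
                )
                entry["mean_abs_error_vs_truth"] = float(err)
            summary["stages"]["deconvolution"] = entry

        if "pathway" in stages:
            current = "pathway"
            collection = (
                enr_mod.read_gmt(config["inputs"]["gmt"])
                if config["inputs"]["gmt"]
                else state["gene_sets"]
            )
            scores = enr_mod.pathway_activity(state["logcpm"], collection)
            scores.round(6).to_csv(outdir / "pathway_scores.tsv", sep="\t")
            summary["stages"]["pathway"] = {"n_sets_scored": int(len(scores))}

        if "risk" in stages:
            current = "risk"
            if config["inputs"]["survival"]:
                surv = pd.read_csv(
                    config["inputs"]["survival"], sep="\t", index_col=0
                )
                risk_expr = state["logcpm"]
            else:
                surv, risk_expr = _simulate_survival_cohort(config, state)
            candidates = list(state["iface_a"]["gene"]) if "iface_a" in state else list(
                risk_expr.index[:50]
            )
            candidates = [g for g in candidates if g in risk_expr.index]
            screen = surv_mod.screen_genes(risk_expr, candidates, surv)
            screen.round(6).to_csv(outdir / "cox_univariate.tsv", sep="\t")
            risk_genes = surv_mod.select_risk_genes(
                screen, p_threshold=float(thresholds["cox_p"])
            )
            entry: dict = {"n_screened": int(len(screen)), "n_risk_genes": len(risk_genes)}
            if risk_genes:
                model = surv_mod.fit_risk_model(risk_genes, risk_expr, surv)
                labels, lr_stat, lr_p, km = surv_mod.stratify_and_compare(
                    model.scores, surv
                )
                with open(outdir / "risk_model.json", "w") as fh:
                    json.dump(
                        {
                            "genes": model.genes,
                            "betas": model.betas.tolist(),
                            "concordance": model.concordance,
                        },
                        fh,
                        indent=1,
                    )
                km.round(6).to_csv(outdir / "km_curves.tsv", sep="\t")
                entry.update(
                    {
                        "concordance": model.concordance,
                        "logrank_p": lr_p,
                        "n_high": int((labels == "high").sum()),
                        "n_low": int((labels == "low").sum()),
                    }
                )
            summary["stages"]["risk"] = entry
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def _simulate_survival_cohort(config: dict, state: dict):
    """Survival demo cohort: expression of the screened genes drives hazard.

    A fresh cohort is simulated whose per-sample expression of a handful of
    planted risk genes enters the hazard with known coefficients, so the Cox
    screen and risk model act on data with ground truth.
    """
    seed = int(config["seed"])
    n = int(config["simulate"]["n_survival"])
    rng = np.random.default_rng(seed + 5)
    if "iface_a" in state and len(state["iface_a"]):
        genes = list(state["iface_a"]["gene"])
    else:
        genes = list(state["logcpm"].index[:30])
    genes = genes[:30]
    x = rng.normal(0.0, 1.0, size=(n, len(genes)))
    betas = np.zeros(len(genes))
    n_risk = min(3, len(genes))
    betas[:n_risk] = 0.8
    surv = sim_mod.generate_survival(
        n, x, betas, baseline_rate=0.002, censor_rate=0.001, seed=seed + 6
    )
    expr = pd.DataFrame(
        (x * 1.5 + 8.0).T, index=genes, columns=surv.index
    )
    expr.attrs["normalization"] = "log2"
    return surv, expr
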