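"""End-to-end orchestration from one declarative configuration.

Stages run in the analysis order: (simulate or load) expression →
differential expression → interaction network + modules → ORA/GSEA →
regulator–module enrichment → regulator–TF links → key genes →
diagnostic model → qPCR quantification. Every stage writes plain TSV /
GMT / JSON outputs and a manifest records seeds, thresholds, and row
counts, so a rerun with the same configuration reproduces every file
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, io, netmod, qpcr, regulators
from .datatypes import ExpressionData
from .enrichment import GeneSetCollection, gsea, ora, read_gmt, write_gmt
from .model import fit_lasso_path, predict_prob, roc_auc
from .netmod import ModuleDetectionConfig
from .simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_ct_table,
    simulate_expression,
    simulate_network,
    simulate_regulator_db,
)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "stage_seed"]

_STAGES = ("simulate", "de", "network", "enrichment", "regulators",
           "key_genes", "model", "pcr")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: adding a stage never perturbs the others."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimulationConfig | None = None
    inputs: dict = field(default_factory=dict)
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    min_edge_score: float = netmod.MEDIUM_CONFIDENCE
    module_penalty: float = 2.0
    overlap_threshold: float = 0.8
    module_min_size: int = 5
    module_max_p: float = 0.05
    gsea_permutations: int = 1000
    gsea_weight: float = 1.0
    gsea_metric: str = "t"  # or "log2fc"
    regulator_min_score: float = 0.5
    tf_min_score: float = 0.3
    min_modules: int = 2
    promising_min_modules: int = 3
    key_gene_top_n: int = 15
    model_n_lambda: int = 100
    model_lambda_min_ratio: float = 0.001
    model_n_folds: int | None = None
    pcr_true_fold_change: float = 4.0
    pcr_ct_noise_sd: float = 0.1
    pcr_n_case: int = 7
    pcr_n_control: int = 6

    def module_config(self) -> ModuleDetectionConfig:
        return ModuleDetectionConfig(
            penalty=self.module_penalty,
            overlap_threshold=self.overlap_threshold,
            min_edge_score=self.min_edge_score,
            min_size=self.module_min_size,
            max_p=self.module_max_p,
        )


_PROFILES = diffexpr.THRESHOLD_PROFILES


def validate_config(source) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML path or a dict.

    Unknown keys are rejected by name; a threshold ``profile`` ("strict"
    or "relaxed") expands to (lfc_threshold, alpha); contradictory values
    (alpha <= 0, negative counts) are rejected.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})

    known = {f.name for f in dataclasses.fields(PipelineConfig)} | {"profile"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")

    profile = raw.pop("profile", None)
    if profile is not None:
        if profile not in _PROFILES:
            raise ValueError(f"unknown threshold profile {profile!r}")
        lfc, alpha = _PROFILES[profile]
        raw.setdefault("lfc_threshold", lfc)
        raw.setdefault("alpha", alpha)

    sim = raw.pop("simulate", None)
    cfg = PipelineConfig(**raw)
    if sim is not None:
        sim = dict(sim)
        sim.setdefault("seed", stage_seed(cfg.seed, "simulate"))
        cfg.simulate = SimulationConfig(**sim)
    elif not cfg.inputs:
        raise ValueError("config needs either a 'simulate' block or 'inputs' paths")

    if cfg.alpha <= 0:
        raise ValueError("alpha must be positive")
    if cfg.lfc_threshold <= 0:
        raise ValueError("lfc_threshold must be positive")
    if cfg.gsea_permutations < 1:
        raise ValueError("gsea_permutations must be >= 1")
    return cfg


def _truth_gmt(truth: GroundTruth) -> GeneSetCollection:
    mods = truth.modules()
    return GeneSetCollection(
        sets={m: sorted(g) for m, g in mods.items()},
        descriptions={m: "planted module" for m in mods},
    )


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute all stages and return the run directory."""
    out = io.ensure_dir(outdir)
    manifest: dict = {
        "config": _config_echo(config),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "stages": {},
    }

    # --- inputs: simulate or load -------------------------------------
    if config.simulate is not None:
        sim = config.simulate
        data, truth = simulate_expression(sim)
        network_full, truth = simulate_network(sim, truth)
        reg_db, truth = simulate_regulator_db(sim, truth)
        reg_db = regulators.load_regulator_db(reg_db)
        collection = _truth_gmt(truth)
        io.write_expression(data, out / "expression.tsv", out / "samples.tsv")
        io.write_network(network_full, out / "edges.tsv")
        io.write_tsv(reg_db, out / "regulator_db.tsv")
        write_gmt(collection, out / "gene_sets.gmt")
        (out / "ground_truth.json").write_text(truth.to_json())
        edge_table = network_full.edge_table()
        manifest["stages"]["simulate"] = {
            "n_genes": int(data.values.shape[0]),
            "n_samples": int(data.values.shape[1]),
            "n_edges": int(len(edge_table)),
            "n_regulator_pairs": int(len(reg_db)),
        }
    else:
        paths = config.inputs
        data = io.read_expression(paths["expression"], paths["annotation"], paths["case"])
        if "probe_annotation" in paths:
            mapping = io.read_probe_annotation(paths["probe_annotation"])
            data = diffexpr.collapse_probes(data, mapping)
        edge_table = io.read_edge_table(paths["edges"])
        reg_db = regulators.load_regulator_db(io.read_tsv(paths["regulators"]))
        collection = read_gmt(paths["gene_sets"])
        truth = None
        manifest["stages"]["simulate"] = {"skipped": True}

    # --- differential expression --------------------------------------
    de_raw, params = diffexpr.fit_moderated_test(data)
    de = diffexpr.call_degs(de_raw, config.lfc_threshold, config.alpha)
    io.write_tsv(de.drop(columns=["zero_var"]), out / "de_table.tsv")
    degs = de.loc[de["call"] != "none", "gene"]
    manifest["stages"]["de"] = {
        **diffexpr.deg_counts(de),
        "d0": None if np.isinf(params.d0) else round(float(params.d0), 6),
        "s0_sq": round(float(params.s0_sq), 10),
        "lfc_threshold": config.lfc_threshold,
        "alpha": config.alpha,
    }

    # --- network + modules (over DEGs, as in the source study design) --
    deg_set = set(degs)
    sub_edges = edge_table[
        edge_table.iloc[:, 0].isin(deg_set) & edge_table.iloc[:, 1].isin(deg_set)
    ]
    network = netmod.build_network(sub_edges, config.min_edge_score)
    modules = netmod.detect_modules(network, config.module_config())
    mod_frame = netmod.modules_to_frame(modules)
    io.write_network(network, out / "network_filtered.tsv")
    io.write_tsv(mod_frame, out / "modules.tsv")
    if len(mod_frame):
        write_gmt(
            GeneSetCollection(
                sets={r.module: r.members.split(";") for r in mod_frame.itertuples()}
            ),
            out / "modules.gmt",
        )
    else:
        (out / "modules.gmt").write_text("")
    manifest["stages"]["network"] = {
        "n_nodes": network.n_nodes,
        "n_edges": network.n_edges,
        "n_modules": len(modules),
        "module_genes": int(len(set().union(*[m.members for m in modules]))) if modules else 0,
        "min_edge_score": config.min_edge_score,
    }

    # --- enrichment (ORA of DEGs, GSEA of the full ranking) ------------
    universe = list(data.values.index)
    ora_table = ora(list(degs), collection, universe, alpha=config.alpha)
    metric = "t" if config.gsea_metric == "t" else "log2fc"
    ranking = pd.Series(de[metric].to_numpy(), index=de["gene"].to_numpy())
    gsea_table = gsea(
        ranking, collection,
        weight_exponent=config.gsea_weight,
        n_permutations=config.gsea_permutations,
        seed=stage_seed(config.seed, "enrichment"),
    )
    io.write_tsv(ora_table, out / "ora.tsv")
    io.write_tsv(gsea_table, out / "gsea.tsv")
    manifest["stages"]["enrichment"] = {
        "ora_sets_tested": int(len(ora_table)),
        "ora_significant": int(ora_table["significant"].sum()) if len(ora_table) else 0,
        "gsea_sets_tested": int(len(gsea_table)),
        "gsea_significant": int(gsea_table["significant"].sum()) if len(gsea_table) else 0,
    }

    # --- regulator inference -------------------------------------------
    reg_filtered = regulators.filter_regulator_pairs(reg_db, config.regulator_min_score)
    module_genes = set().union(*[m.members for m in modules]) if modules else set()
    reg_universe = module_genes | (set(reg_filtered["target"]) & set(universe))
    if modules and reg_universe and len(reg_filtered):
        reg_results = regulators.regulator_module_enrichment(
            reg_filtered, modules, reg_universe,
            min_modules=config.min_modules, alpha=config.alpha,
        )
    else:
        reg_results = pd.DataFrame(
            columns=["regulator", "class", "module", "k", "module_size",
                     "n_targets", "universe_size", "p"]
        )
    tf_pairs = regulators.regulator_tf_network(reg_db, reg_results, config.tf_min_score)
    promising = regulators.select_promising_candidates(
        reg_results, config.promising_min_modules
    )
    io.write_tsv(reg_results, out / "regulator_modules.tsv")
    io.write_tsv(tf_pairs, out / "regulator_tf.tsv")
    io.write_tsv(regulators.partner_counts(tf_pairs), out / "regulator_tf_counts.tsv")
    (out / "promising.json").write_text(json.dumps(promising, indent=2))
    manifest["stages"]["regulators"] = {
        "pairs_after_score_filter": int(len(reg_filtered)),
        "regulator_module_pairs": int(len(reg_results)),
        "n_regulators": int(reg_results["regulator"].nunique()) if len(reg_results) else 0,
        "ncrna_tf_links": int(len(tf_pairs)),
        "promising": promising,
    }

    # --- key genes ------------------------------------------------------
    key = regulators.rank_key_genes(de, network, top_n=config.key_gene_top_n)
    io.write_tsv(key, out / "key_genes.tsv")
    manifest["stages"]["key_genes"] = {"n_ranked": int(len(key))}

    # --- diagnostic model ------------------------------------------------
    if len(degs) >= 1:
        X = data.values.loc[degs].T
        fit = fit_lasso_path(
            X, data.groups.to_numpy(),
            n_folds=config.model_n_folds,
            seed=stage_seed(config.seed, "model"),
            n_lambda=config.model_n_lambda,
            lambda_min_ratio=config.model_lambda_min_ratio,
            case_label=data.case,
        )
        prob = predict_prob(fit, X)
        roc = roc_auc(prob, (data.groups == data.case).astype(int).to_numpy())
        (out / "model.json").write_text(
            json.dumps(fit.to_dict(), sort_keys=True, indent=2)
        )
        io.write_tsv(
            pd.DataFrame({
                "threshold": roc.thresholds,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
            }),
            out / "roc.tsv",
        )
        manifest["stages"]["model"] = {
            "n_features_in": int(X.shape[1]),
            "n_selected": int(len(fit.selected_genes)),
            "lambda_selected": float(fit.lambda_selected),
            "cv_deviance_min": round(float(fit.cv_deviance.min()), 10),
            "training_auc": round(roc.auc, 10),
        }
    else:
        (out / "model.json").write_text("{}")
        manifest["stages"]["model"] = {"skipped": "no DEGs"}

    # --- qPCR quantification (synthetic measurements per candidate) ------
    pcr_rows = []
    for i, candidate in enumerate(manifest["stages"]["regulators"]["promising"]):
        ct = simulate_ct_table(
            config.pcr_n_case, config.pcr_n_control,
            config.pcr_true_fold_change, config.pcr_ct_noise_sd,
            seed=stage_seed(config.seed, f"pcr:{candidate}"),
            target=candidate,
        )
        res = qpcr.quantify_and_test(ct, [candidate])
        pcr_rows.append(res)
    pcr_table = (
        pd.concat(pcr_rows, ignore_index=True)
        if pcr_rows
        else pd.DataFrame(columns=["gene", "case_fold_change", "p", "verdict"])
    )
    io.write_tsv(pcr_table, out / "pcr_validation.tsv")
    manifest["stages"]["pcr"] = {
        "n_tested": int(len(pcr_table)),
        "n_significant": int((pcr_table["verdict"] == "significant").sum())
        if len(pcr_table) else 0,
    }

    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n"
    )
    return out


def _config_echo(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
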