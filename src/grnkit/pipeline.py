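"""End-to-end orchestration from one YAML config.

Stage order: simulate → per-(timepoint, condition) consensus inference →
prior overlay → contextualization against the preceding-time-point (and
treated-vs-control) differential tables → hub topology and cross-network
comparison → gene-set over-representation → promoter-accessibility
concordance. A manifest records the config hash, seed, and the row count
and content hash of every output, so byte-identical reruns are verifiable
from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import io as gio
from .inference import InferenceParams, bootstrap_consensus
from .multiomics import assign_peaks_to_genes, correlate_fold_changes
from .refine import contextualize, overlay_prior
from .simulate import (
    SimulationDesign,
    corrupt_prior,
    derive_differential_tables,
    sample_truth_network,
    simulate_accessibility,
    simulate_timecourse,
    synthetic_de_table,
)
from .io import concat_expression
from .topology import compare_networks, compute_hubs, hypergeom_enrichment

__all__ = ["PipelineConfig", "run_all", "config_hash"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {
        "n_tf": 30,
        "mean_out_degree": 2.0,
        "activation_fraction": 0.7,
        "noise_sd": 0.5,
        "prior_false_negative_rate": 0.2,
        "prior_false_positive_rate": 0.2,
        "n_multiomic_genes": 1000,
        "n_off_target_peaks": 100,
    },
    "design": {
        "timepoints": ["0h", "24h", "72h"],
        "conditions": ["control", "treated"],
        "replicates": 3,
        "alpha": 0.05,
        "accessibility_rho": 0.45,
    },
    "inference": {
        "n_trees": 100,
        "candidates_per_split": "sqrt",
        "min_samples_leaf": 1,
    },
    "consensus": {"B": 20, "tau": 0.5},
    "overlay": {"mode": "intersect"},
    "contextualize": {"strict_roots": True, "unsigned_justifies": True},
    "pool_adjacent": True,
    "promoter_window": 2000,
    "thresholds": {"de_alpha": 0.05, "acc_fdr": 0.05, "fold_threshold": 2.0},
    "top_k_hubs": 10,
}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def config_hash(config: Mapping[str, Any]) -> str:
    """sha256 of the canonical JSON form of a config mapping."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration (defaults merged in)."""

    raw: dict[str, Any]

    def __post_init__(self) -> None:
        cfg = _deep_merge(DEFAULT_CONFIG, self.raw)
        tau = cfg["consensus"]["tau"]
        if not 0 < tau < 1:
            raise ValueError(f"consensus.tau must lie in (0, 1), got {tau}")
        if cfg["consensus"]["B"] < 2:
            raise ValueError("consensus.B must be ≥ 2")
        for key in ("de_alpha", "acc_fdr"):
            v = cfg["thresholds"][key]
            if not 0 < v < 1:
                raise ValueError(f"thresholds.{key} must lie in (0, 1), got {v}")
        if cfg["thresholds"]["fold_threshold"] <= 1:
            raise ValueError("thresholds.fold_threshold must be > 1")
        if cfg["overlay"]["mode"] not in ("intersect", "annotate"):
            raise ValueError(f"unknown overlay mode {cfg['overlay']['mode']!r}")
        if cfg["promoter_window"] <= 0:
            raise ValueError("promoter_window must be > 0")
        object.__setattr__(self, "raw", cfg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(data)

    def __getitem__(self, key: str) -> Any:
        return self.raw[key]

    @property
    def hash(self) -> str:
        return config_hash(self.raw)


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _count_rows(path: Path) -> int:
    with open(path, encoding="utf-8") as fh:
        return sum(1 for ln in fh if ln.strip() and not ln.startswith("#"))


def run_all(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute every stage, write all outputs under ``outdir``, return the
    manifest (also written as ``manifest.json``).

    Identical config + seed give byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.raw
    seed = int(cfg["seed"])
    chash = config.hash
    tag = f"config_hash: {chash}"
    design = SimulationDesign(
        timepoints=tuple(cfg["design"]["timepoints"]),
        conditions=tuple(cfg["design"]["conditions"]),
        replicates=int(cfg["design"]["replicates"]),
        alpha=float(cfg["design"]["alpha"]),
        accessibility_rho=float(cfg["design"]["accessibility_rho"]),
    )
    outputs: dict[str, Path] = {}
    counts: dict[str, int] = {}

    def register(name: str, path: Path) -> None:
        outputs[name] = path

    # ---- stage 1: ground truth + expression -------------------------------
    sim = cfg["simulate"]
    truth = sample_truth_network(
        n_tf=int(sim["n_tf"]),
        mean_out_degree=float(sim["mean_out_degree"]),
        activation_fraction=float(sim["activation_fraction"]),
        noise_sd=float(sim["noise_sd"]),
        seed=seed,
    )
    gio.write_edge_list(truth.network, outdir / "truth_network.tsv", tag)
    register("truth_network", outdir / "truth_network.tsv")
    mats = simulate_timecourse(truth, design)
    for cond, mat in mats.items():
        p = outdir / f"expression_{cond}.tsv"
        m = outdir / f"samples_{cond}.tsv"
        gio.write_expression_matrix(mat, p, m, tag)
        register(f"expression_{cond}", p)
        register(f"samples_{cond}", m)
    combined = concat_expression([mats[c] for c in design.conditions])
    logger.info("simulated %d genes × %d samples", combined.n_genes, combined.n_samples)

    # ---- stage 2: curated prior (noisy truth) -----------------------------
    prior = corrupt_prior(
        truth,
        float(sim["prior_false_negative_rate"]),
        float(sim["prior_false_positive_rate"]),
        seed=seed,
    )
    gio.write_edge_list(prior, outdir / "prior_network.tsv", tag)
    register("prior_network", outdir / "prior_network.tsv")

    # ---- stage 3: differential tables -------------------------------------
    contrasts = []
    for cond in design.conditions:
        for prev, cur in zip(design.timepoints, design.timepoints[1:]):
            contrasts.append(((cur, cond), (prev, cond)))
    if len(design.conditions) >= 2:
        base, treated = design.conditions[0], design.conditions[1]
        for tp in design.timepoints[1:]:
            contrasts.append(((tp, treated), (tp, base)))
    de_tables = derive_differential_tables(combined, contrasts, design.alpha)
    for name, table in de_tables.items():
        p = outdir / f"de_{name}.tsv"
        gio.write_differential_table(table, p, tag)
        register(f"de_{name}", p)

    # ---- stage 4: per-(timepoint, condition) networks ---------------------
    params = InferenceParams(
        n_trees=int(cfg["inference"]["n_trees"]),
        candidates_per_split=cfg["inference"]["candidates_per_split"],
        min_samples_leaf=int(cfg["inference"]["min_samples_leaf"]),
        seed=seed,
    )
    regulators = list(truth.gene_ids)
    contextualized: dict[tuple[str, str], Any] = {}
    stage_counts = []
    for cond in design.conditions:
        for prev, tp in zip(design.timepoints, design.timepoints[1:]):
            label = f"{tp}_{cond}"
            sample_ids = combined.samples_where(timepoint=tp, condition=cond)
            if cfg["pool_adjacent"]:
                sample_ids = (
                    combined.samples_where(timepoint=prev, condition=cond) + sample_ids
                )
            sub = combined.subset_samples(sample_ids)
            consensus, support = bootstrap_consensus(
                sub,
                regulators,
                params,
                B=int(cfg["consensus"]["B"]),
                tau=float(cfg["consensus"]["tau"]),
            )
            gio.write_edge_list(consensus, outdir / f"consensus_{label}.tsv", tag)
            register(f"consensus_{label}", outdir / f"consensus_{label}.tsv")
            overlaid = overlay_prior(consensus, prior, mode=cfg["overlay"]["mode"])
            gio.write_edge_list(overlaid, outdir / f"overlaid_{label}.tsv", tag)
            register(f"overlaid_{label}", outdir / f"overlaid_{label}.tsv")
            de_name = f"{tp}_{cond}_vs_{prev}_{cond}"
            input_nodes = (
                truth.treatment_module
                if cond != design.conditions[0]
                else frozenset()
            )
            result = contextualize(
                overlaid,
                de_tables[de_name].calls(),
                input_nodes,
                strict_roots=bool(cfg["contextualize"]["strict_roots"]),
                unsigned_justifies=bool(cfg["contextualize"]["unsigned_justifies"]),
            )
            contextualized[(tp, cond)] = result.pruned
            gio.write_edge_list(
                result.pruned, outdir / f"contextualized_{label}.tsv", tag
            )
            register(f"contextualized_{label}", outdir / f"contextualized_{label}.tsv")
            removal_path = outdir / f"removals_{label}.tsv"
            with open(removal_path, "w", encoding="utf-8") as fh:
                fh.write(f"# {tag}\n")
                result.removed.to_csv(fh, sep="\t", index=False, lineterminator="\n")
            register(f"removals_{label}", removal_path)
            stage_counts.append(
                {
                    "network": label,
                    "consensus_edges": consensus.n_edges,
                    "overlaid_edges": overlaid.n_edges,
                    "contextualized_edges": result.pruned.n_edges,
                    "contextualized_nodes": len(result.pruned.node_set()),
                    "removed_nodes": len(result.removed),
                }
            )
            logger.info(
                "%s: consensus %d → overlay %d → contextualized %d edges",
                label,
                consensus.n_edges,
                overlaid.n_edges,
                result.pruned.n_edges,
            )

    # ---- stage 5: topology -------------------------------------------------
    for (tp, cond), net in contextualized.items():
        label = f"{tp}_{cond}"
        if net.node_set():
            hubs = compute_hubs(net, top_k=int(cfg["top_k_hubs"]), allow_empty=True)
            p = outdir / f"hubs_{label}.tsv"
            with open(p, "w", encoding="utf-8") as fh:
                fh.write(f"# {tag}\n")
                hubs.to_csv(fh, sep="\t", lineterminator="\n")
            register(f"hubs_{label}", p)
    comparison_rows = []
    for cond in design.conditions:
        tps = design.timepoints[1:]
        for a, b in zip(tps, tps[1:]):
            cmp_ = compare_networks(contextualized[(a, cond)], contextualized[(b, cond)])
            comparison_rows.append(
                {
                    "network_a": f"{a}_{cond}",
                    "network_b": f"{b}_{cond}",
                    "shared_nodes": cmp_.n_shared_nodes,
                    "unique_to_a": cmp_.n_unique_to_a,
                    "unique_to_b": cmp_.n_unique_to_b,
                    "shared_edges": cmp_.n_shared_edges,
                }
            )
    if len(design.conditions) >= 2:
        base, treated = design.conditions[0], design.conditions[1]
        for tp in design.timepoints[1:]:
            cmp_ = compare_networks(contextualized[(tp, base)], contextualized[(tp, treated)])
            comparison_rows.append(
                {
                    "network_a": f"{tp}_{base}",
                    "network_b": f"{tp}_{treated}",
                    "shared_nodes": cmp_.n_shared_nodes,
                    "unique_to_a": cmp_.n_unique_to_a,
                    "unique_to_b": cmp_.n_unique_to_b,
                    "shared_edges": cmp_.n_shared_edges,
                }
            )
    cmp_path = outdir / "network_comparisons.tsv"
    with open(cmp_path, "w", encoding="utf-8") as fh:
        fh.write(f"# {tag}\n")
        pd.DataFrame(comparison_rows).to_csv(fh, sep="\t", index=False, lineterminator="\n")
    register("network_comparisons", cmp_path)

    # ---- stage 6: over-representation of the treated network --------------
    universe = list(truth.gene_ids)
    gene_sets = {"treatment_module": set(truth.treatment_module)}
    import numpy as _np

    rng = _np.random.default_rng(_np.random.SeedSequence(entropy=seed, spawn_key=(9,)))
    for i in range(3):
        size = max(3, len(universe) // 5)
        members = rng.choice(universe, size=size, replace=False)
        gene_sets[f"random_set_{i + 1}"] = set(members.tolist())
    gio.write_gene_sets(gene_sets, outdir / "gene_sets.tsv", tag)
    register("gene_sets", outdir / "gene_sets.tsv")
    if len(design.conditions) >= 2:
        treated = design.conditions[1]
        tp = design.timepoints[1]
        query = sorted(contextualized[(tp, treated)].node_set())
        enr = hypergeom_enrichment(query, gene_sets, universe)
        p = outdir / f"enrichment_{tp}_{treated}.tsv"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write(f"# {tag}\n")
            enr.to_csv(fh, sep="\t", lineterminator="\n")
        register(f"enrichment_{tp}_{treated}", p)

    # ---- stage 7: accessibility concordance (genome-wide) -----------------
    genome_de = synthetic_de_table(
        n_genes=int(sim["n_multiomic_genes"]),
        alpha=float(cfg["thresholds"]["de_alpha"]),
        seed=seed,
    )
    gio.write_differential_table(genome_de, outdir / "de_genomewide.tsv", tag)
    register("de_genomewide", outdir / "de_genomewide.tsv")
    acc, tss = simulate_accessibility(
        genome_de,
        rho=design.accessibility_rho,
        n_off_target=int(sim["n_off_target_peaks"]),
        seed=seed,
    )
    gio.write_tss_table(tss, outdir / "tss.tsv", tag)
    register("tss", outdir / "tss.tsv")
    assigned = assign_peaks_to_genes(acc, tss, window_bp=int(cfg["promoter_window"]))
    gio.write_peak_table(assigned, outdir / "peaks_assigned.tsv", tag)
    register("peaks_assigned", outdir / "peaks_assigned.tsv")
    report = correlate_fold_changes(
        genome_de,
        assigned,
        de_alpha=float(cfg["thresholds"]["de_alpha"]),
        acc_fdr=float(cfg["thresholds"]["acc_fdr"]),
        fold_threshold=float(cfg["thresholds"]["fold_threshold"]),
    )
    scatter_path = outdir / "fc_concordance.tsv"
    with open(scatter_path, "w", encoding="utf-8") as fh:
        fh.write(f"# {tag}\n")
        fh.write(
            f"# pearson_r: {report.r:.6f}\tp: {report.p:.6g}\t"
            f"n_genes: {report.n_genes}\tslope: {report.slope:.6f}\t"
            f"intercept: {report.intercept:.6f}\n"
        )
        report.records.to_csv(fh, sep="\t", lineterminator="\n")
    register("fc_concordance", scatter_path)
    logger.info(
        "fold-change concordance: r=%.3f over %d genes", report.r, report.n_genes
    )

    # ---- manifest ----------------------------------------------------------
    manifest = {
        "config_hash": chash,
        "seed": seed,
        "config": cfg,
        "stage_counts": stage_counts,
        "concordance": {
            "r": round(report.r, 6),
            "p": float(f"{report.p:.6g}"),
            "n_genes": report.n_genes,
        },
        "outputs": {
            name: {
                "path": str(path.relative_to(outdir)),
                "rows": _count_rows(path),
                "sha256": _file_sha256(path),
            }
            for name, path in sorted(outputs.items())
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
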