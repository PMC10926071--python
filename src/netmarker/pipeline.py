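"""End-to-end orchestration: screen -> network -> modules -> hubs -> subtypes.

One config drives the whole pipeline from either a synthetic simulation
or expression files on disk. A single global seed deterministically
derives per-stage seeds (by hashing the stage name), so any stage can be
reproduced in isolation and two runs with the same seed write identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from netmarker import coexpr_network, module_detection, representatives as reps_mod
from netmarker import screening, subtyping, synthetic
from netmarker.expression_io import (
    ExpressionMatrix,
    attach_groups,
    collapse_probes,
    read_expression,
    read_probe_map,
    read_sample_annotation,
    write_expression,
)

logger = logging.getLogger(__name__)

#: subtyping configurations run by default: SOM on a 2x3 grid, k-means
#: with 3 and 5 targets, a competitive network with 3, hierarchical with 5
DEFAULT_ALGORITHMS: tuple[tuple[str, dict], ...] = (
    ("som", {"rows": 2, "cols": 3}),
    ("kmeans", {"k": 3}),
    ("kmeans", {"k": 5}),
    ("competitive", {"k": 3}),
    ("hierarchical", {"k": 5}),
)


@dataclass
class PipelineConfig:
    """All pipeline parameters. Exactly one input source must be set:
    either ``simulation`` or ``expression_path``."""

    simulation: synthetic.SimulationConfig | None = None
    expression_path: str | None = None
    annotation_path: str | None = None
    probe_map_path: str | None = None
    dialect: str = "tsv"

    measure: str = "variance"
    transform: str | None = None  # resolved per input source when None
    breakpoint_method: str = "piecewise"

    network_mode: str = "auto"
    manual_threshold: float | None = None
    correlation_group: str | None = None

    module_method: str = "kmeans"
    k: int | str = "auto"
    k_range: tuple[int, int] = (1, 10)
    gap_b: int = 20
    kmeans_n_init: int = 10

    paths: str = "hops"

    algorithms: tuple[tuple[str, dict], ...] = DEFAULT_ALGORITHMS
    n_runs: int = 50
    exclude_groups: tuple[str, ...] = ("healthy",)
    standardize: str = "zscore"

    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.expression_path is None):
            raise ValueError("set exactly one input source: simulation or expression_path")

    def resolved_transform(self) -> str:
        if self.transform is not None:
            return self.transform
        if self.simulation is not None and not self.simulation.exponentiate:
            return "none"  # factor-scale values, already roughly log scale
        return "log2_shifted"


@dataclass
class PipelineResult:
    critical_point: screening.CriticalPoint
    n_genes: int
    n_sensitive: int
    network_nodes: int
    network_edges: int
    network_threshold: float
    partition: module_detection.ModulePartition
    representatives: pd.DataFrame
    evaluations: dict[str, dict]
    recovery: dict[str, float] | None
    report: dict[str, Any] = field(default_factory=dict)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest, 16) % (2**31)


def _load_input(config: PipelineConfig) -> tuple[ExpressionMatrix, synthetic.GroundTruth | None]:
    if config.simulation is not None:
        expr, truth = synthetic.simulate(
            config.simulation, seed=stage_seed(config.seed, "simulate")
        )
        return expr, truth
    raw = read_expression(config.expression_path, dialect=config.dialect)
    if config.probe_map_path is not None:
        expr = collapse_probes(raw, read_probe_map(config.probe_map_path))
    else:
        expr = ExpressionMatrix(values=raw.values)
    if config.annotation_path is not None:
        expr = attach_groups(expr, read_sample_annotation(config.annotation_path))
    return expr, None


def run(config: PipelineConfig) -> PipelineResult:
    """Execute all stages; see module docstring. Raises with the stage
    name on any stage failure."""
    stage = "input"
    try:
        expr, truth = _load_input(config)

        stage = "screening"
        if config.measure == "variance":
            measure = screening.gene_variance(expr, transform=config.resolved_transform())
        elif config.measure == "iic":
            measure = screening.iic_measure(expr)
        else:
            raise ValueError(f"unknown measure {config.measure!r}")
        curve = screening.rank_measure(measure)
        cp = screening.detect_critical_point(curve, method=config.breakpoint_method)
        sensitive = screening.select_sensitive_genes(expr, measure, cp)

        stage = "network"
        corr = coexpr_network.cross_correlation(sensitive, group=config.correlation_group)
        net = coexpr_network.threshold_network(
            corr,
            mode=config.network_mode,
            manual_threshold=config.manual_threshold,
            breakpoint_method=config.breakpoint_method,
        )

        stage = "modules"
        if config.module_method == "kmeans":
            feats = module_detection.profile_embedding(
                module_detection.correlation_features(corr).loc[
                    list(net.nodes), list(net.nodes)
                ]
            )
            if config.k == "auto":
                lo, hi = config.k_range
                k, _ = module_detection.gap_statistic(
                    feats,
                    k_range=range(lo, min(hi, len(feats) - 1) + 1),
                    b=config.gap_b,
                    seed=stage_seed(config.seed, "gap"),
                    n_init=config.kmeans_n_init,
                )
            else:
                k = int(config.k)
            partition = module_detection.kmeans_modules(
                feats, k, seed=stage_seed(config.seed, "kmeans"),
                n_init=config.kmeans_n_init,
            )
        elif config.module_method == "louvain":
            partition, _ = module_detection.louvain(
                net, seed=stage_seed(config.seed, "louvain")
            )
        else:
            raise ValueError(f"unknown module method {config.module_method!r}")

        stage = "representatives"
        reps = reps_mod.extract_all(net, partition, paths=config.paths)

        stage = "subtyping"
        evaluations: dict[str, dict] = {}
        features = None
        if expr.groups is not None:
            features = subtyping.build_features(
                expr,
                list(reps["representative"]),
                exclude_groups=config.exclude_groups,
                standardize=config.standardize,
            )
            for algorithm, params in config.algorithms:
                key = algorithm + "_" + "x".join(str(v) for v in params.values())
                evaluations[key] = subtyping.repeat_experiment(
                    features,
                    algorithm,
                    params,
                    n_runs=config.n_runs,
                    base_seed=stage_seed(config.seed, f"subtype:{key}"),
                )

        stage = "recovery"
        recovery = None
        if truth is not None:
            predictions = None
            if features is not None:
                assign = subtyping.run_algorithm(
                    features, "som", {"rows": 2, "cols": 3},
                    seed=stage_seed(config.seed, "recovery_som"),
                )
                predictions = subtyping.map_clusters_to_labels(assign, features.labels)
            recovery = synthetic.score_recovery(
                truth,
                selected_genes=sensitive.gene_ids,
                partition=partition.assignments,
                representatives=list(reps["representative"]),
                predictions=predictions,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    _check_nesting(expr, sensitive, net, partition, reps)

    report: dict[str, Any] = {
        "seed": config.seed,
        "critical_point": {"rank": cp.rank, "threshold": cp.threshold,
                           "confident": cp.confident},
        "n_genes": len(expr.gene_ids),
        "n_sensitive": len(sensitive.gene_ids),
        "network": {
            "nodes": net.number_of_nodes(),
            "edges": net.number_of_edges(),
            "threshold": net.graph["threshold"],
            "isolated_genes": len(net.graph["excluded_genes"]),
        },
        "n_modules": partition.k,
        "representatives": sorted(reps["representative"]),
        "subtyping": {
            key: {
                "accuracy_mean": ev["accuracy_mean"],
                "accuracy_sd": ev["accuracy_sd"],
                "per_class_mean": ev["per_class_mean"].round(6).to_dict(),
            }
            for key, ev in evaluations.items()
        },
        "recovery": recovery,
    }
    result = PipelineResult(
        critical_point=cp,
        n_genes=len(expr.gene_ids),
        n_sensitive=len(sensitive.gene_ids),
        network_nodes=net.number_of_nodes(),
        network_edges=net.number_of_edges(),
        network_threshold=float(net.graph["threshold"]),
        partition=partition,
        representatives=reps,
        evaluations=evaluations,
        recovery=recovery,
        report=report,
    )
    if config.outdir is not None:
        _write_artifacts(config, expr, sensitive, curve, net, partition, reps, result)
    return result


def _check_nesting(expr, sensitive, net, partition, reps) -> None:
    all_genes = set(expr.gene_ids)
    sens = set(sensitive.gene_ids)
    module_genes = set(partition.assignments.index)
    rep_genes = set(reps["representative"])
    if not (rep_genes <= module_genes <= sens <= all_genes):
        raise AssertionError("gene-set nesting violated across stages")
    if not set(net.nodes) <= sens:
        raise AssertionError("network contains genes outside the sensitive set")


def _write_artifacts(config, expr, sensitive, curve, net, partition, reps, result) -> None:
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    write_expression(sensitive, os.path.join(out, "sensitive_genes.tsv"))
    pd.DataFrame(
        {"rank": range(1, len(curve.values) + 1), "gene": curve.gene_ids,
         "value": curve.values}
    ).to_csv(os.path.join(out, "ranked_curve.tsv"), sep="\t", index=False)
    coexpr_network.write_edge_list(net, os.path.join(out, "network_edges.tsv"))
    module_detection.write_partition(partition, os.path.join(out, "modules.tsv"))
    reps_mod.write_representatives(reps, os.path.join(out, "representatives.tsv"))
    rows = []
    for key, ev in result.evaluations.items():
        for cls, metrics in ev["per_class_mean"].iterrows():
            rows.append(
                {"algorithm": key, "class": cls, **metrics.round(6).to_dict(),
                 "accuracy_mean": round(ev["accuracy_mean"], 6)}
            )
    pd.DataFrame(rows).to_csv(os.path.join(out, "subtype_summary.tsv"),
                              sep="\t", index=False)
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True, default=str)


def config_from_yaml(path: str) -> PipelineConfig:
    """Build a config from a flat YAML file; unknown keys are rejected."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    sim = data.pop("simulation", None)
    if sim is not None:
        sim = synthetic.SimulationConfig(**sim)
    names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "algorithms" in data:
        data["algorithms"] = tuple((a, dict(p)) for a, p in data["algorithms"])
    if "k_range" in data:
        data["k_range"] = tuple(data["k_range"])
    if "exclude_groups" in data:
        data["exclude_groups"] = tuple(data["exclude_groups"])
    return PipelineConfig(simulation=sim, **data)
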