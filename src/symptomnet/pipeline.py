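"""End-to-end orchestration: prepare -> estimate -> communities -> bridge ->
bootstrap -> report, plus the between-disorder edge arithmetic of the report.

The run report summarizes the estimated network the way the study's results
section does: community count, positive/negative between-disorder edge
counts, the percentage of possible between-disorder edges realized (one
decimal, half away from zero), and the top bridge symptoms per index.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import bridge as bridge_mod
from .communities import Partition, walktrap
from .data_prep import SymptomData, prepare_matrix, read_symptom_csv, reliability
from .elasso import EstimationConfig, estimate_network, write_thresholds_json
from .errors import ConfigError, DataError, SymptomNetError
from .graph import NetworkGraph
from .ising import GeneratorConfig, generate_cohort
from .stability import bootstrap_edges

__all__ = [
    "PipelineConfig",
    "count_between_cluster",
    "round_half_away",
    "run_pipeline",
    "rebuild_report",
]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (so 2.75 -> 2.8, -2.75 -> -2.8)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def count_between_cluster(
    graph: NetworkGraph,
    disorder_labels,
    roster_sizes: tuple[int, int] | None = None,
) -> tuple[int, int, int, float]:
    """Count between-disorder edges by sign and the share of possible pairs.

    Returns (positive, negative, possible, percentage). ``possible`` is the
    product of the two disorder roster sizes; pass ``roster_sizes`` to count
    a full roster that includes nodes excluded from the network (the default
    uses the nodes present in the graph). The percentage is 100 * positive /
    possible, rounded to one decimal half away from zero.
    """
    if isinstance(disorder_labels, dict):
        arr = np.array([disorder_labels[l] for l in graph.labels])
    else:
        arr = np.asarray(list(disorder_labels))
    if arr.size != graph.p:
        raise DataError("disorder labels must cover every node in the graph")
    groups = sorted(set(arr))
    if len(groups) != 2:
        raise DataError(
            f"expected exactly two disorder groups, got {len(groups)}: {groups}"
        )
    if roster_sizes is None:
        possible = int((arr == groups[0]).sum() * (arr == groups[1]).sum())
    else:
        possible = int(roster_sizes[0] * roster_sizes[1])
    positive = negative = 0
    for i, j, w in graph.edges():
        if arr[i] != arr[j]:
            if w > 0:
                positive += 1
            else:
                negative += 1
    percentage = round_half_away(100.0 * positive / possible, 1)
    return positive, negative, possible, percentage


@dataclasses.dataclass
class PipelineConfig:
    """Full run configuration; either ``input_csv`` or ``generator`` is set."""

    input_csv: str | None = None
    generator: GeneratorConfig | None = None
    estimation: EstimationConfig = dataclasses.field(default_factory=EstimationConfig)
    walk_length: int = 4
    bootstrap_B: int | None = 1000
    bootstrap_seed: int = 0
    reliability_seed: int = 0
    min_rows: int = 50
    out_dir: str = "symptomnet_run"
    #: Denominator convention for the between-disorder percentage: the full
    #: disorder rosters as configured (zero-variance exclusions still count)
    #: unless disabled.
    full_roster_denominator: bool = True

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.generator is None):
            raise ConfigError("exactly one of input_csv or generator must be set")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            raw = json.load(handle)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if kwargs.get("generator") is not None:
            gen = dict(kwargs["generator"])
            for key in ("cluster_sizes", "within_weight_range", "bridge_weight_range"):
                if key in gen:
                    gen[key] = tuple(gen[key])
            if "forced_edges" in gen:
                gen["forced_edges"] = tuple(tuple(e) for e in gen["forced_edges"])
            kwargs["generator"] = GeneratorConfig(**gen)
        if kwargs.get("estimation") is not None:
            kwargs["estimation"] = EstimationConfig(**kwargs["estimation"])
        else:
            kwargs.pop("estimation", None)
        return cls(**kwargs)


def _top_bridges(table: pd.DataFrame, column: str, k: int = 3) -> list[str]:
    ranked = table.sort_values([column, "label"], ascending=[False, True])
    return [str(l) for l in ranked["label"].head(k)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all artifacts to ``out_dir``.

    Returns the run report (also serialized as ``report.json``). The run is
    a pure function of the input file (or generator seed) and the
    configuration; no timestamps enter any artifact.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": []}

    def stage(name: str) -> None:
        report["stages"].append(name)

    try:
        # ---- input -----------------------------------------------------
        if config.generator is not None:
            stage("generate")
            frame, truth = generate_cohort(config.generator)
            frame.to_csv(out / "data.csv", index=False)
            truth.write_json(out / "ground_truth.json")
            report["generator_seed"] = config.generator.seed
            roster = (
                int(config.generator.cluster_sizes[0]),
                int(config.generator.cluster_sizes[1]),
            )
        else:
            stage("read")
            frame = read_symptom_csv(config.input_csv)
            roster = None

        # ---- preparation ----------------------------------------------
        stage("prepare")
        data, prep_log = prepare_matrix(frame, min_rows=config.min_rows)
        with open(out / "prep_log.json", "w", encoding="utf-8") as handle:
            json.dump(prep_log, handle, indent=2)
        if roster is None or not config.full_roster_denominator:
            counts = pd.Series(data.cluster_labels).value_counts()
            clusters = sorted(set(data.cluster_labels))
            roster = (int(counts[clusters[0]]), int(counts[clusters[1]]))
        rel = reliability(data, split_seed=config.reliability_seed)
        report["reliability"] = {
            "kr20": rel.kr20,
            "split_half": rel.split_half,
            "split_seed": config.reliability_seed,
        }

        # ---- estimation ------------------------------------------------
        stage("estimate")
        graph, params = estimate_network(data, config.estimation)
        graph.write_adjacency_csv(out / "adjacency.csv")
        graph.write_edge_csv(out / "edges.csv")
        graph.write_graphml(out / "network.graphml")
        write_thresholds_json(params, graph.labels, out / "thresholds.json")

        # ---- communities -----------------------------------------------
        stage("communities")
        partition = walktrap(graph, t=config.walk_length)
        partition.write_json(out / "partition.json")

        # ---- bridge ----------------------------------------------------
        stage("bridge")
        table = bridge_mod.bridge_table(
            graph, data.cluster_labels, endorsement_rates=data.endorsement_rates()
        )
        table.to_csv(out / "bridge.csv", index=False)

        # ---- bootstrap (optional) --------------------------------------
        if config.bootstrap_B is not None:
            stage("bootstrap")
            summary = bootstrap_edges(
                data,
                config.estimation,
                B=config.bootstrap_B,
                seed=config.bootstrap_seed,
                point_graph=graph,
            )
            summary.write_csv(out / "bootstrap_ci.csv", nonzero_only=True)
            summary.write_overlap_json(out / "bootstrap_overlap.json")
            report["bootstrap"] = summary.overlap_summary()
            report["bootstrap"]["seed"] = config.bootstrap_seed

        # ---- report ----------------------------------------------------
        stage("report")
        positive, negative, possible, percentage = count_between_cluster(
            graph, data.cluster_labels, roster_sizes=roster
        )
        report.update(
            {
                "n": data.n,
                "p": data.p,
                "n_dropped_rows": prep_log["n_dropped_rows"],
                "dropped_columns": prep_log["dropped_columns"],
                "n_edges": graph.n_edges,
                "n_communities": partition.n_communities,
                "modularity": partition.modularity,
                "between_cluster": {
                    "positive_edges": positive,
                    "negative_edges": negative,
                    "possible_pairs": possible,
                    "percentage_realized": percentage,
                },
                "top_bridge_symptoms": {
                    "strength": _top_bridges(table, "bridge_strength"),
                    "betweenness": _top_bridges(table, "bridge_betweenness"),
                    "closeness": _top_bridges(table, "bridge_closeness"),
                },
                "artifacts": sorted(f.name for f in out.iterdir() if f.is_file()),
                "estimation": {
                    "gamma": config.estimation.gamma,
                    "rule": config.estimation.rule,
                    "n_lambda": config.estimation.n_lambda,
                    "lambda_min_ratio": config.estimation.lambda_min_ratio,
                },
                "walk_length": config.walk_length,
            }
        )
    except SymptomNetError as err:
        failed_stage = report["stages"][-1] if report["stages"] else "setup"
        marker = out / "FAILED"
        marker.write_text(f"stage {failed_stage}: {err}\n", encoding="utf-8")
        raise type(err)(f"stage {failed_stage!r} failed: {err}") from err

    report["artifacts"] = sorted(
        f.name for f in out.iterdir() if f.is_file() and f.name != "report.json"
    )
    with open(out / "report.json", "w", encoding="utf-8") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
    return report


def rebuild_report(out_dir) -> dict:
    """Recompute the between-disorder summary from the serialized artifacts.

    Reads ``adjacency.csv`` plus ``partition.json`` and recounts edges; used
    to verify that report percentages recompute exactly from the edge list.
    """
    out = Path(out_dir)
    graph = NetworkGraph.read_adjacency_csv(out / "adjacency.csv")
    from .data_prep import infer_cluster_labels

    disorder = infer_cluster_labels(graph.labels)
    with open(out / "report.json", encoding="utf-8") as handle:
        report = json.load(handle)
    possible = report["between_cluster"]["possible_pairs"]
    counts = pd.Series(disorder).value_counts()
    roster_from_graph = int(counts.iloc[0] * counts.iloc[1])
    positive, negative, _, _ = count_between_cluster(graph, disorder)
    percentage = round_half_away(100.0 * positive / possible, 1)
    return {
        "positive_edges": positive,
        "negative_edges": negative,
        "possible_pairs": possible,
        "possible_pairs_in_graph": roster_from_graph,
        "percentage_realized": percentage,
    }
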