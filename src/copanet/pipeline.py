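"""End-to-end orchestration: ingest → inference → criteria → hierarchy → compare.

`analyze` drives the whole analysis on in-memory tables and returns rich
result objects; `run_pipeline` wraps it with file IO, export writing, and a
JSON report validated against the schema shipped with the package.  Given an
identical configuration (including the seed) the report is byte-identical
across runs.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import assoc, criteria as criteria_mod, hierarchy, ingest
from .errors import StageError
from .networks import DisorderNetwork

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    posts_path: str = ""
    mapping_path: str = ""
    criteria_path: str = ""
    bot_list_path: str | None = None
    out_dir: str = "copanet_out"
    year_window: tuple[str, str] = ("2022-01-01", "2023-01-01")
    max_posts: int = 365
    alpha: float = assoc.DEFAULT_ALPHA
    n_reps: int = assoc.DEFAULT_N_REPS
    swaps_multiplier: int = assoc.DEFAULT_SWAPS_MULTIPLIER
    n_null: int = hierarchy.DEFAULT_N_NULL
    ensemble: str = "shared"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("max_posts", "n_reps", "swaps_multiplier", "n_null"):
            if getattr(self, name) <= 0:
                raise StageError("config", "invalid-param",
                                 f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise StageError("config", "invalid-param", "alpha must be in (0,1)")
        if self.seed is None:
            raise StageError("config", "missing-seed",
                             "seed is mandatory for stochastic stages")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "year_window" in raw:
            raw["year_window"] = tuple(raw["year_window"])
        return cls(**raw)


@dataclass
class PipelineResult:
    positive: DisorderNetwork
    negative: DisorderNetwork
    criteria_net: DisorderNetwork
    classified: pd.DataFrame
    partition_pos: hierarchy.Partition
    partition_crit: hierarchy.Partition
    modularity_pos: hierarchy.ModularityResult
    modularity_crit: hierarchy.ModularityResult
    comparison: hierarchy.ComparisonResult
    dendrogram_pos: hierarchy.Dendrogram
    dendrogram_crit: hierarchy.Dendrogram
    summary: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)


def _network_summary(net: DisorderNetwork, categories: dict[str, str]) -> dict:
    comps, isolates = assoc.giant_component(net)
    intra, inter = assoc.category_edge_counts(net, categories)
    return {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "density": round(net.density, 3),
        "giant_component_size": len(comps[0]) if comps else 0,
        "n_isolated": len(isolates),
        "intra_category_edges": intra,
        "inter_category_edges": inter,
    }


def _modularity_summary(res: hierarchy.ModularityResult,
                        part: hierarchy.Partition) -> dict:
    return {
        "q_w": round(res.q_w, 6),
        "expected_q_null": round(res.expected_q_null, 6),
        "delta_q": round(res.delta_q, 6),
        "n_clusters": res.n_clusters,
        "unclustered": part.singletons(),
    }


def analyze(posts: pd.DataFrame, mapping: pd.DataFrame,
            criteria_table: pd.DataFrame, config: PipelineConfig
            ) -> PipelineResult:
    """Run inference, criteria network, clustering, and comparison in memory.

    ``posts`` must already be filtered (see :func:`ingest.filter_posts`);
    `run_pipeline` handles filtering and IO around this function.
    """
    categories = dict(zip(mapping["icd10_l4"], mapping["icd10_l2"]))

    graph = ingest.build_bipartite(posts, mapping)
    user_sets = graph.user_sets()
    n_users_per_disorder = {d: len(s) for d, s in user_sets.items()}

    observed = assoc.observed_overlaps(graph)
    nulls = assoc.null_overlap_stats(graph, n_reps=config.n_reps,
                                     swaps_multiplier=config.swaps_multiplier,
                                     seed=config.seed)
    table = observed.merge(nulls, on=["disorder_a", "disorder_b"])
    classified = assoc.classify_pairs(table, alpha=config.alpha)
    positive, negative = assoc.build_networks(classified, categories,
                                              n_users_per_disorder)

    crit_net = criteria_mod.build_criteria_network(
        criteria_table, restrict_to=set(positive.graph.nodes),
        categories=categories)

    results = {}
    for name, net in (("coposting", positive), ("criteria", crit_net)):
        nodes, dist = hierarchy.distance_matrix(net)
        dend = hierarchy.average_linkage(nodes, dist)
        part, mod = hierarchy.optimal_cut(dend, net, n_null=config.n_null,
                                          seed=config.seed,
                                          ensemble=config.ensemble)
        results[name] = (dend, part, mod)

    dend_pos, part_pos, mod_pos = results["coposting"]
    dend_crit, part_crit, mod_crit = results["criteria"]
    comparison = hierarchy.compare_networks(positive, part_pos,
                                            crit_net, part_crit)
    return PipelineResult(
        positive=positive, negative=negative, criteria_net=crit_net,
        classified=classified,
        partition_pos=part_pos, partition_crit=part_crit,
        modularity_pos=mod_pos, modularity_crit=mod_crit,
        comparison=comparison,
        dendrogram_pos=dend_pos, dendrogram_crit=dend_crit,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Full file-based run; writes exports and returns the JSON report."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def stage(name):
        log.info("stage %s at %.1fs", name, time.time() - t0)

    try:
        stage("ingest")
        posts, _rejects = ingest.load_posts(config.posts_path)
        mapping = ingest.load_mapping(config.mapping_path)
        criteria_table = ingest.load_criteria(config.criteria_path)
        bots = (ingest.load_bot_list(config.bot_list_path)
                if config.bot_list_path else set())
        posts = ingest.filter_posts(posts, window=config.year_window,
                                    max_posts=config.max_posts, bot_list=bots)
    except FileNotFoundError as exc:
        raise StageError("ingest", "file-not-found", str(exc)) from exc

    graph = ingest.build_bipartite(posts, mapping)
    dataset = ingest.dataset_summary(posts, graph, mapping)

    stage("infer")
    result = analyze(posts, mapping, criteria_table, config)
    categories = dict(zip(mapping["icd10_l4"], mapping["icd10_l2"]))

    stage("export")
    result.classified.to_csv(out_dir / "pairs.csv", index=False)
    for name, net in (("positive", result.positive),
                      ("negative", result.negative),
                      ("criteria", result.criteria_net)):
        net.edge_dataframe().to_csv(out_dir / f"{name}_edges.csv", index=False)
        net.to_graphml(out_dir / f"{name}.graphml")
    assoc.node_metrics(result.positive, categories).to_csv(
        out_dir / "node_metrics.csv", index=False)
    graph.to_edge_dataframe().to_csv(out_dir / "bipartite_edges.csv",
                                     index=False)
    for name, dend, part in (
            ("coposting", result.dendrogram_pos, result.partition_pos),
            ("criteria", result.dendrogram_crit, result.partition_crit)):
        (out_dir / f"{name}_dendrogram.nwk").write_text(dend.to_newick() + "\n")
        pd.DataFrame(sorted(part.labels.items()),
                     columns=["icd10_code", "cluster_id"]).to_csv(
            out_dir / f"{name}_partition.csv", index=False)

    report = {
        "seed": config.seed,
        "dataset": dataset,
        "positive_network": _network_summary(result.positive, categories),
        "negative_network": _network_summary(result.negative, categories),
        "criteria_network": _network_summary(result.criteria_net, categories),
        "hierarchy": {
            "coposting": _modularity_summary(result.modularity_pos,
                                             result.partition_pos),
            "criteria": _modularity_summary(result.modularity_crit,
                                            result.partition_crit),
        },
        "comparison": {
            "ari": round(result.comparison.ari, 6),
            "nmi": round(result.comparison.nmi, 6),
            "edge_jaccard": round(result.comparison.edge_jaccard, 6),
            "shared_edge_fraction": [round(f, 6) for f in
                                     result.comparison.shared_edge_fraction],
        },
    }
    validate_report(report)
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    stage("done")
    return report


# ---------------------------------------------------------------------------
# report schema validation (self-contained checker for the shipped schema)

def _load_schema() -> dict:
    with resources.files("copanet").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


_TYPES = {"object": dict, "array": list, "integer": int, "number": (int, float),
          "string": str}


def _check(value, schema, root, path):
    if "$ref" in schema:
        key = schema["$ref"].split("/")[-1]
        return _check(value, root["definitions"][key], root, path)
    typ = schema.get("type")
    if typ and not isinstance(value, _TYPES[typ]):
        raise ValueError(f"report field {path or '<root>'} should be {typ}")
    if typ == "integer" and isinstance(value, bool):
        raise ValueError(f"report field {path} should be integer")
    if typ == "object":
        for req in schema.get("required", []):
            if req not in value:
                raise ValueError(f"report missing field {path}/{req}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                _check(value[key], sub, root, f"{path}/{key}")


def validate_report(report: dict) -> None:
    """Validate a report dict against the shipped JSON schema; raises on error."""
    schema = _load_schema()
    _check(report, schema, schema, "")
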