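"""End-to-end orchestration: binarize -> filter -> fit -> metrics -> hubs ->
communities -> permutation tests -> shortest-path reports.

Every run writes a machine-readable manifest (config, config hash, package
version, seeds, output list) sufficient to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, community, io, metrics
from .instruments import (
    DEFAULT_PREVALENCE_FRACTION,
    binarize_table,
    filter_items,
    item_columns,
    load_instrument_specs,
    paired_totals_tests,
    scale_totals,
)
from .ising import DEFAULT_EBIC_GAMMA, DEFAULT_LAMBDA_MIN_RATIO, DEFAULT_N_LAMBDAS, IsingNetwork, fit_ising, to_absolute_network
from .metrics import DEFAULT_HUB_MIN_MEASURES, DEFAULT_HUB_TOP_FRACTION
from .permutation import DEFAULT_N_PERMUTATIONS, benjamini_hochberg, permutation_null

logger = logging.getLogger(__name__)

TIME_POINTS = ("PRE", "POST")


class PipelineError(RuntimeError):
    """A stage-named pipeline failure."""


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; round-trips through YAML unchanged."""

    input_csv: str
    output_dir: str
    prevalence_fraction: float = DEFAULT_PREVALENCE_FRACTION
    filter_per_time_point: bool = True
    ebic_gamma: float = DEFAULT_EBIC_GAMMA
    edge_rule: str = "AND"
    n_lambdas: int = DEFAULT_N_LAMBDAS
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO
    hub_top_fraction: float = DEFAULT_HUB_TOP_FRACTION
    hub_min_measures: int = DEFAULT_HUB_MIN_MEASURES
    community_restarts: int = 10
    n_permutations: int = DEFAULT_N_PERMUTATIONS
    permutation_measure: str = "clustering"
    permutation_paired: bool = False
    permutation_nodes: list[str] | None = None
    significance_threshold: float = 0.015
    apply_bh_correction: bool = False
    seed: int = 0
    run_communities: bool = True
    run_permutation: bool = True
    run_path_report: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence_fraction < 1.0:
            raise ValueError("prevalence_fraction must lie in (0, 1)")
        if self.edge_rule not in ("AND", "OR"):
            raise ValueError("edge_rule must be 'AND' or 'OR'")
        if not 0.0 < self.hub_top_fraction <= 1.0:
            raise ValueError("hub_top_fraction must lie in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 < self.significance_threshold <= 1.0:
            raise ValueError("significance_threshold must lie in (0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def report_shortest_paths(net: IsingNetwork, focus_node: str, hub_set) -> list[dict]:
    """Canonical shortest path from a focus node to each hub.

    Returns one row per (focus, hub) pair with the path length and the node
    sequence (lexicographically smallest among equal geodesics); unreachable
    hubs are reported with an infinite length and no sequence.
    """
    labels = list(net.node_labels)
    for node in [focus_node, *hub_set]:
        if node not in labels:
            raise ValueError(f"node {node!r} not in network")
    sp = metrics.shortest_paths(metrics.edge_lengths(net))
    i = labels.index(focus_node)
    rows = []
    for hub in hub_set:
        j = labels.index(hub)
        path_idx = sp.path(i, j)
        rows.append(
            {
                "focus": focus_node,
                "hub": hub,
                "length": float(sp.distances[i, j]),
                "path": [labels[k] for k in path_idx] if path_idx is not None else None,
            }
        )
    return rows


def _format_path_report(rows: list[dict]) -> list[str]:
    lines = ["pair\tpath"]
    for r in rows:
        pair = f"{r['focus']} -> {r['hub']}"
        if r["path"] is None:
            lines.append(f"{pair}\tunreachable")
        else:
            seq = " -> ".join(r["path"])
            lines.append(f"{pair}\t{seq} (length {r['length']:.6g})")
    return lines


def _safe_name(label: str) -> str:
    return label.replace(": ", "_").replace(" ", "_").replace("/", "_")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; writes the result bundle and returns it in memory."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    results: dict = {"config": config}

    def _write(name: str, writer) -> Path:
        path = out_dir / name
        writer(path)
        outputs.append(name)
        return path

    # ---- binarize -------------------------------------------------------
    try:
        specs = load_instrument_specs()
        raw = io.read_response_csv(config.input_csv)
        binary = binarize_table(raw, specs)
    except Exception as exc:
        raise PipelineError(f"stage 'binarize' failed: {exc}") from exc
    _write("binary_responses.csv", lambda p: io.write_response_csv(binary, p))

    # ---- scale totals & paired t-tests ---------------------------------
    try:
        totals = scale_totals(raw, specs)
        ttests = paired_totals_tests(totals)
    except Exception as exc:
        raise PipelineError(f"stage 'totals' failed: {exc}") from exc
    _write("scale_totals.csv", lambda p: io.write_table_csv(totals, p))
    _write("paired_t_tests.csv", lambda p: io.write_table_csv(ttests, p))

    # ---- node selection -------------------------------------------------
    try:
        retained = filter_items(binary, config.prevalence_fraction, config.filter_per_time_point)
    except Exception as exc:
        raise PipelineError(f"stage 'filter' failed: {exc}") from exc
    if not retained:
        raise PipelineError("stage 'filter' failed: no nodes retained")
    _write("retained_nodes.txt", lambda p: io.write_lines(retained, p))
    results["retained_nodes"] = retained

    kept = binary.loc[:, ["participant_id", "time_point", *retained]]
    n_missing = int(kept[retained].isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d record(s) with missing items in the retained node set", n_missing)
        kept = kept.dropna(subset=retained)

    # ---- network estimation --------------------------------------------
    nets: dict[str, IsingNetwork] = {}
    abs_nets: dict[str, IsingNetwork] = {}
    tables: dict[str, pd.DataFrame] = {}
    for tp in TIME_POINTS:
        sub = kept[kept["time_point"] == tp]
        if sub.empty:
            raise PipelineError(f"stage 'fit' failed: no records at time point {tp}")
        tables[tp] = sub
        try:
            net = fit_ising(
                sub, gamma=config.ebic_gamma, rule=config.edge_rule,
                n_lambdas=config.n_lambdas, lambda_min_ratio=config.lambda_min_ratio,
            )
        except Exception as exc:
            raise PipelineError(f"stage 'fit' ({tp}) failed: {exc}") from exc
        nets[tp] = net
        abs_nets[tp] = to_absolute_network(net)
        _write(f"network_signed_{tp}.tsv", lambda p, n=net: n.save(p, str(p).replace(".tsv", ".json")))
        outputs.append(f"network_signed_{tp}.json")
        _write(f"network_abs_{tp}.tsv", lambda p, n=abs_nets[tp]: n.save(p, str(p).replace(".tsv", ".json")))
        outputs.append(f"network_abs_{tp}.json")
    results["networks"] = nets
    results["abs_networks"] = abs_nets

    # ---- centralities & hubs -------------------------------------------
    hub_sets: dict[str, list[str]] = {}
    cent: dict[str, pd.DataFrame] = {}
    for tp in TIME_POINTS:
        table = metrics.centrality_table(abs_nets[tp], config.hub_top_fraction, config.hub_min_measures)
        cent[tp] = table
        hubs = metrics.detect_hubs(table, config.hub_top_fraction, config.hub_min_measures)
        hub_sets[tp] = hubs
        _write(f"centrality_{tp}.csv", lambda p, t=table: io.write_table_csv(t, p))
        _write(f"hubs_{tp}.txt", lambda p, h=hubs: io.write_lines(h, p))
    hub_union = sorted(set(hub_sets["PRE"]) | set(hub_sets["POST"]), key=list(retained).index)
    _write("hubs_union.txt", lambda p: io.write_lines(hub_union, p))
    results["centrality"] = cent
    results["hubs"] = {**hub_sets, "union": hub_union}

    # ---- communities ----------------------------------------------------
    if config.run_communities:
        partitions = {}
        for tp in TIME_POINTS:
            part = community.optimize_partition(abs_nets[tp], seed=config.seed, n_restarts=config.community_restarts)
            partitions[tp] = part
            logger.info("%s partition: %d modules, codelength %.4f bits", tp, part.n_modules, part.codelength)
            df = pd.DataFrame({"node": list(part.module_of_node), "module": list(part.module_of_node.values())})
            _write(f"communities_{tp}.csv", lambda p, d=df: io.write_table_csv(d, p))
        results["partitions"] = partitions

    # ---- permutation tests ---------------------------------------------
    significant: list[str] = []
    if config.run_permutation:
        nodes = config.permutation_nodes or retained
        rows = []
        perm_results = {}
        for k, node in enumerate(nodes):
            try:
                res = permutation_null(
                    tables["PRE"], tables["POST"], node,
                    measure=config.permutation_measure,
                    n_permutations=config.n_permutations,
                    seed=config.seed + k,
                    paired=config.permutation_paired,
                    gamma=config.ebic_gamma, rule=config.edge_rule,
                    n_lambdas=config.n_lambdas, lambda_min_ratio=config.lambda_min_ratio,
                )
            except Exception as exc:
                raise PipelineError(f"stage 'permutation' ({node}) failed: {exc}") from exc
            perm_results[node] = res
            rows.append(
                {
                    "node": node,
                    "measure": res.measure,
                    "pre": res.observed_pre,
                    "post": res.observed_post,
                    "diff": res.observed_diff,
                    "p_value": res.p_value,
                    "n_permutations": res.n_permutations,
                    "n_redraws": res.n_redraws,
                }
            )
        perm_df = pd.DataFrame(rows)
        if config.apply_bh_correction:
            perm_df["q_value"] = benjamini_hochberg(perm_df["p_value"].to_numpy())
            significant = perm_df.loc[perm_df["q_value"] < config.significance_threshold, "node"].tolist()
        else:
            significant = perm_df.loc[perm_df["p_value"] < config.significance_threshold, "node"].tolist()
        _write("permutation_results.csv", lambda p: io.write_table_csv(perm_df, p))
        results["permutation"] = perm_results
        results["significant_nodes"] = significant

    # ---- shortest-path reports -----------------------------------------
    if config.run_path_report and significant and hub_union:
        for tp in TIME_POINTS:
            lines = []
            for node in significant:
                hubs = [h for h in hub_union if h != node]
                rows = report_shortest_paths(abs_nets[tp], node, hubs)
                lines.extend(_format_path_report(rows)[1:] if lines else _format_path_report(rows))
            _write(f"shortest_paths_{tp}.txt", lambda p, ls=lines: io.write_lines(ls, p))

    # ---- manifest -------------------------------------------------------
    manifest = {
        "package": "empathnet",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "retained_nodes": retained,
        "hubs": {"PRE": hub_sets["PRE"], "POST": hub_sets["POST"], "union": hub_union},
        "significant_nodes": significant,
        "outputs": sorted(set(outputs)),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    results["manifest"] = manifest
    return results
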