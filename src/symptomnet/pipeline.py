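"""End-to-end four-group analysis: residualize -> per-group networks ->
centralities -> comparisons -> stability, plus an average force-directed
layout, gathered into a single report with full provenance.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centrality import centrality_table
from .comparison import edge_count_test, nct_all
from .ggm import SymptomNetwork, estimate_network
from .io import CohortTable, load_item_metadata, read_cohort_csv, write_edge_list
from .residualize import residualize_items
from .simulate import four_group_fixture
from .stability import bootstrap_edges, case_dropping, cs_coefficient

logger = logging.getLogger(__name__)

CATEGORY_COLORS = {
    "negative_attitude": "pink",
    "performance_difficulty": "green",
    "somatic_elements": "blue",
}

DEFAULT_CONFIG = {
    "input": None,                      # cohort CSV path, or None to simulate
    "schema": None,                     # column-name mapping for read_cohort_csv
    "simulate": {"preset": "trace-four-group"},
    "seed": 0,
    "residualize": {"scope": "per_group"},
    "estimator": {"gamma": 0.5, "n_lambda": 100, "lambda_min_ratio": 0.01},
    "comparison": {"enabled": True, "n_permutations": 5000},
    "stability": {
        "enabled": True,
        "groups": None,                 # None = all groups
        "n_boot_edges": 2500,
        "n_boot_cases": 1000,
        "proportions": None,            # None = default grid 0.05..0.75
    },
    "layout": {"enabled": True},
    "output_dir": None,
}


def _merge_config(config: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if k not in cfg:
            raise ValueError(f"unknown config key: {k!r}")
        if isinstance(cfg[k], dict) and isinstance(v, dict):
            unknown = set(v) - set(cfg[k])
            if unknown:
                raise ValueError(f"unknown config key(s) under {k!r}: {sorted(unknown)}")
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        return _merge_config(yaml.safe_load(fh) or {})


@dataclass
class AnalysisReport:
    """Everything needed to regenerate the figures' analogues without
    re-running estimation."""

    networks: dict                      # group -> SymptomNetwork
    centralities: pd.DataFrame          # long: group x item x measure
    residual_group_means: pd.DataFrame
    edge_count_tests: pd.DataFrame | None
    nct_results: pd.DataFrame | None
    edge_bootstraps: dict               # group -> EdgeBootstrapResult
    cs_coefficients: dict               # group -> {measure: CS}
    layout: pd.DataFrame | None
    provenance: dict

    def to_dict(self) -> dict:
        d = {
            "provenance": self.provenance,
            "groups": {
                g: {
                    "n": net.n,
                    "nonzero_edge_count": net.nonzero_edge_count,
                    "lambda_selected": net.lambda_selected,
                    "gamma": net.gamma,
                    "edges": net.edges(),
                }
                for g, net in self.networks.items()
            },
            "residual_group_means": json.loads(self.residual_group_means.to_json(orient="index")),
            "centralities": json.loads(self.centralities.to_json(orient="records")),
        }
        if self.edge_count_tests is not None:
            d["edge_count_tests"] = json.loads(self.edge_count_tests.to_json(orient="records"))
        if self.nct_results is not None:
            d["nct"] = json.loads(self.nct_results.to_json(orient="records"))
        if self.cs_coefficients:
            d["cs_coefficients"] = self.cs_coefficients
        if self.layout is not None:
            d["layout"] = json.loads(self.layout.to_json(orient="records"))
        return d

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
        for g, net in self.networks.items():
            write_edge_list(net, out / f"edges_{g}.csv")
        self.centralities.to_csv(out / "centrality.csv", index=False)
        comps = []
        if self.edge_count_tests is not None:
            comps.append(self.edge_count_tests.assign(test="edge_count_chi2"))
        if self.nct_results is not None:
            comps.append(self.nct_results.assign(test="nct"))
        if comps:
            pd.concat(comps, ignore_index=True).to_csv(out / "comparisons.csv", index=False)
        for g, res in self.edge_bootstraps.items():
            res.table.to_csv(out / f"stability_{g}.csv", index=False)
        if self.layout is not None:
            self.layout.to_csv(out / "layout.csv", index=False)


def average_layout(networks: dict, seed=None, p: int | None = None) -> np.ndarray:
    """Fruchterman-Reingold layout of the element-wise mean of the groups'
    absolute weight matrices; coordinates rescaled to the unit square.
    Deterministic given ``seed``."""
    mats = [np.abs(np.asarray(n.W if hasattr(n, "W") else n, dtype=float))
            for n in networks.values()]
    if not mats:
        raise ValueError("need at least one network")
    A = np.mean(mats, axis=0)
    p = A.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(p))
    for i in range(p):
        for j in range(i + 1, p):
            if A[i, j] > 0:
                G.add_edge(i, j, weight=A[i, j])
    pos = nx.spring_layout(G, weight="weight", seed=seed)
    xy = np.array([pos[i] for i in range(p)], dtype=float)
    span = xy.max(axis=0) - xy.min(axis=0)
    xy = np.where(span > 0, (xy - xy.min(axis=0)) / np.where(span > 0, span, 1.0), 0.5)
    return xy


def _load_cohort(cfg: dict, rng: np.random.Generator) -> CohortTable:
    if cfg["input"] is not None:
        return read_cohort_csv(cfg["input"], schema=cfg["schema"])
    preset = cfg["simulate"].get("preset", "trace-four-group")
    if preset != "trace-four-group":
        raise ValueError(f"unknown simulation preset: {preset!r}")
    cohorts, _ = four_group_fixture(seed=int(rng.integers(0, 2**31 - 1)))
    from .simulate import concat_cohorts

    return concat_cohorts(cohorts)


def run_pipeline(config: dict | str | Path | None = None) -> AnalysisReport:
    """Run the full analysis described by ``config`` (dict or YAML path).

    Stages: load/simulate cohort -> residualize -> estimate one network per
    group -> centralities -> cross-group comparisons -> stability
    diagnostics -> average layout. Optional stages can be toggled off;
    toggles never change the outputs of the stages that do run. All
    randomness derives from the single top-level ``seed``.
    """
    if config is None or isinstance(config, dict):
        cfg = _merge_config(config)
    else:
        cfg = load_config(config)
    rng = np.random.default_rng(cfg["seed"])
    # stage seeds drawn up front so toggling a stage does not shift the others
    seeds = {k: int(s) for k, s in zip(
        ["simulate", "comparison", "stab_edges", "stab_cases", "layout"],
        rng.integers(0, 2**31 - 1, size=5),
    )}

    t0 = time.time()
    cohort = _load_cohort(cfg, np.random.default_rng(seeds["simulate"]))
    for g, sub in cohort.by_group().items():
        if sub.n < 2:
            raise ValueError(f"group {g!r} has fewer than 2 rows")
    logger.info("pipeline: cohort loaded n=%d p=%d groups=%s (%.1fs)",
                cohort.n, cohort.p, cohort.groups, time.time() - t0)

    resid = residualize_items(cohort, scope=cfg["residualize"]["scope"])
    resid_means = residualize_items(cohort, scope="pooled").group_means()

    est = dict(cfg["estimator"])
    networks: dict[str, SymptomNetwork] = {}
    cents = []
    for g in cohort.groups:
        net = estimate_network(resid.for_group(g), **est)
        networks[g] = net
        ct = centrality_table(net.W, item_names=cohort.item_names)
        ct.insert(0, "group", g)
        cents.append(ct)
        logger.info("pipeline: group %s nonzero edges=%d lambda=%.4g",
                    g, net.nonzero_edge_count, net.lambda_selected)
    centralities = pd.concat(cents, ignore_index=True)

    ect = nct_df = None
    if cfg["comparison"]["enabled"] and len(networks) >= 2:
        t0 = time.time()
        ect = edge_count_test(networks).table
        nct_df = nct_all(resid, B=cfg["comparison"]["n_permutations"],
                         seed=seeds["comparison"], estimator=est)
        logger.info("pipeline: comparisons done (%.1fs)", time.time() - t0)

    boots, cs = {}, {}
    if cfg["stability"]["enabled"]:
        t0 = time.time()
        sgroups = cfg["stability"]["groups"] or cohort.groups
        props = cfg["stability"]["proportions"]
        for g in sgroups:
            boots[g] = bootstrap_edges(resid.for_group(g),
                                       B=cfg["stability"]["n_boot_edges"],
                                       seed=seeds["stab_edges"], estimator=est)
            cd = case_dropping(resid.for_group(g),
                               **({"proportions": props} if props else {}),
                               B=cfg["stability"]["n_boot_cases"],
                               seed=seeds["stab_cases"], estimator=est)
            cs[g] = cs_coefficient(cd)
        logger.info("pipeline: stability done (%.1fs)", time.time() - t0)

    layout = None
    if cfg["layout"]["enabled"]:
        xy = average_layout(networks, seed=seeds["layout"])
        layout = pd.DataFrame({"item": cohort.item_names,
                               "x": xy[:, 0], "y": xy[:, 1]})
        if cohort.p == 21:
            meta = load_item_metadata()
            layout["category"] = [m.category for m in meta]
            layout["color"] = [CATEGORY_COLORS[m.category] for m in meta]

    report = AnalysisReport(
        networks=networks,
        centralities=centralities,
        residual_group_means=resid_means,
        edge_count_tests=ect,
        nct_results=nct_df,
        edge_bootstraps=boots,
        cs_coefficients=cs,
        layout=layout,
        provenance={
            "version": __version__,
            "config": {k: v for k, v in cfg.items() if k != "output_dir"},
            "stage_seeds": seeds,
            "residualize_scope": cfg["residualize"]["scope"],
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
    )
    if cfg["output_dir"]:
        report.write(cfg["output_dir"])
    return report
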