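"""Stage orchestration: synthetic simulate → project → topology → enrich → prioritize.

Each stage is a plain function over the library modules; the CLI and the
analysis drivers are thin wrappers around these.  Every stochastic stage
consumes an explicit seed from the configuration, so two runs with equal
configuration produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__, io
from .bipartite import ActivityTable, build_bipartite, summarize
from .druggability import prioritize, score_targets
from .neighborhood import DistanceProfiler, MarkerSets, enrichment, map_symbols
from .projection import project
from .synthetic_data import SyntheticConfig, gen_activity, gen_markers, gen_ppi
from .topology import clustering_profile, degree_distribution, diameter, fit_power_law

log = logging.getLogger("assaynet")

DEFAULTS: dict = {
    "synthetic": dataclasses.asdict(SyntheticConfig()),
    "inputs": None,  # {"activity":…, "assay_meta":…, "ppi":…, "markers": {name: path}}
    "projection": {"min_jaccard": 0.10, "drop_isolates": False},
    "enrichment": {"n_random": 1000, "rng_seed": 0},
    "prioritize": {"bin_width": 0.5, "min_degree": 17},
}

MARKER_NAMES = ("essential", "drug_targets", "disease_genes", "bioassay_targets")


class PipelineConfigError(ValueError):
    pass


def load_config(path: Optional[str] = None, seed: Optional[int] = None) -> dict:
    """Merge a YAML config file over the built-in defaults.

    ``seed`` overrides both the synthetic rng_seed and the enrichment
    rng_seed, so a single command-line flag controls all randomness.
    """
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULTS.items()}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        for section, value in user.items():
            if section not in cfg:
                raise PipelineConfigError(f"unknown config section {section!r}")
            if isinstance(value, dict) and isinstance(cfg[section], dict):
                cfg[section].update(value)
            else:
                cfg[section] = value
    if seed is not None:
        cfg["synthetic"]["rng_seed"] = int(seed)
        cfg["enrichment"]["rng_seed"] = int(seed)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Fail before any computation when neither inputs nor synthetic block
    is usable."""
    inputs = cfg.get("inputs")
    if inputs is not None:
        required = {"activity", "assay_meta", "ppi", "markers"}
        missing = required - set(inputs)
        if missing:
            raise PipelineConfigError(
                f"inputs block missing keys: {sorted(missing)}")
    else:
        SyntheticConfig(**cfg["synthetic"])  # raises ConfigError if invalid
    pj = cfg["projection"]["min_jaccard"]
    if not 0 < pj <= 1:
        raise PipelineConfigError("projection.min_jaccard must be in (0,1]")
    if cfg["enrichment"]["n_random"] < 1:
        raise PipelineConfigError("enrichment.n_random must be >= 1")


def _write_log(out: Path, cfg: dict) -> None:
    with (out / "run.log").open("w", encoding="utf-8") as fh:
        fh.write(f"assaynet {__version__}\n")
        fh.write(f"networkx {nx.__version__}, numpy {np.__version__}, "
                 f"scipy {scipy.__version__}, pandas {pd.__version__}\n")
        fh.write("config:\n")
        fh.write(yaml.safe_dump(cfg, sort_keys=True))


def stage_simulate(cfg: dict, out: Path):
    """Generate PPI + markers + activity table and write them as TSV."""
    scfg = SyntheticConfig(**cfg["synthetic"])
    ppi = gen_ppi(scfg.n_proteins, scfg.attach_m, scfg.rng_seed)
    markers = gen_markers(ppi, scfg)
    table = gen_activity(scfg, markers)
    io.write_edges(ppi, out / "ppi_edges.tsv")
    for name, members in markers.as_dict().items():
        io.write_markers(members, out / f"markers_{name}.txt")
    io.write_activity(table, out / "activity.tsv", out / "assays.tsv")
    return ppi, markers, table


def load_inputs(cfg: dict) -> tuple[nx.Graph, MarkerSets, ActivityTable]:
    """Inputs from files when configured, else from the synthetic block."""
    inputs = cfg.get("inputs")
    if inputs is None:
        scfg = SyntheticConfig(**cfg["synthetic"])
        ppi = gen_ppi(scfg.n_proteins, scfg.attach_m, scfg.rng_seed)
        markers = gen_markers(ppi, scfg)
        return ppi, markers, gen_activity(scfg, markers)
    ppi = io.read_edges(inputs["ppi"])
    sets = {}
    for name in MARKER_NAMES:
        symbols = io.read_markers(inputs["markers"][name])
        mapped, unmapped = map_symbols(symbols, ppi)
        if unmapped:
            log.warning("%d %s symbols not in the PPI network", len(unmapped), name)
        sets[name] = frozenset(mapped)
    markers = MarkerSets(**sets)
    table = io.read_activity(inputs["activity"], inputs["assay_meta"])
    return ppi, markers, table


def stage_project(table: ActivityTable, cfg: dict, out: Path) -> nx.Graph:
    """Bipartite build + summary + Jaccard projection, with exports."""
    net = build_bipartite(table)
    s = summarize(net)
    io.write_table(
        [[s.n_assays_active, s.n_active_compounds, s.n_pairs,
          s.mean_compounds_per_assay, s.mean_assays_per_compound]],
        out / "bipartite_summary.tsv",
        columns=["n_assays_active", "n_active_compounds", "n_pairs",
                 "mean_compounds_per_assay", "mean_assays_per_compound"])
    assay_net = project(net, cfg["projection"]["min_jaccard"],
                        drop_isolates=cfg["projection"]["drop_isolates"])
    io.write_graphml(assay_net, out / "assay_network.graphml")
    return assay_net


def stage_topology(assay_net: nx.Graph, out: Path) -> dict:
    dist = degree_distribution(assay_net)
    io.write_table(sorted(dist.pk.items()), out / "degree_distribution.tsv",
                   columns=["k", "pk"])
    row: dict = {"n_nodes": assay_net.number_of_nodes(),
                 "n_edges": assay_net.number_of_edges()}
    try:
        fit = fit_power_law(dist)
        row.update(exponent=fit.exponent, pearson_r=fit.pearson_r,
                   r_squared=fit.r_squared, n_fit_points=fit.n_points)
    except ValueError:
        log.warning("degree distribution too narrow for a power-law fit")
    prof = clustering_profile(assay_net)
    row.update(clustering_mean=prof.overall_mean, clustering_sd=prof.overall_sd)
    if assay_net.number_of_edges() > 0:
        row["diameter"] = diameter(assay_net)
    io.write_table([row.values()], out / "topology.tsv", columns=list(row))
    return row


def stage_enrich(ppi: nx.Graph, markers: MarkerSets, cfg: dict, out: Path):
    """Bioassay-target enrichment around each anchor set, with the
    randomised control, one table row per (anchor, distance)."""
    prof = DistanceProfiler(ppi)
    n_random = cfg["enrichment"]["n_random"]
    rng_seed = cfg["enrichment"]["rng_seed"]
    rows = []
    results = {}
    anchors = {"essential": markers.essential,
               "drug_targets": markers.drug_targets,
               "disease_genes": markers.disease_genes}
    for name, seeds in anchors.items():
        if not seeds or not markers.bioassay_targets:
            log.warning("skipping enrichment around %s (empty set)", name)
            continue
        res = enrichment(ppi, seeds, markers.bioassay_targets,
                         n_random=n_random, rng_seed=rng_seed, profiler=prof)
        results[name] = res
        for d in res.distances:
            rows.append([name, d, res.mean_fraction[d],
                         res.random_mean_fraction[d], res.p_value[d],
                         res.n_seeds, res.n_random])
    io.write_table(rows, out / "enrichment.tsv",
                   columns=["anchor_set", "distance", "mean_fraction",
                            "random_mean_fraction", "p_value",
                            "n_seeds", "n_random"])
    return results


def stage_prioritize(ppi: nx.Graph, markers: MarkerSets, cfg: dict, out: Path):
    """Characteristic distances and binned ranking of bioassay targets."""
    candidates = markers.bioassay_targets - markers.drug_targets
    rows = score_targets(ppi, candidates, markers.essential,
                         markers.drug_targets)
    ranked = prioritize(rows, bin_width=cfg["prioritize"]["bin_width"],
                        min_degree=cfg["prioritize"]["min_degree"],
                        exclude=markers.drug_targets)
    io.write_table(
        [[r.gene, f"{r.d_essential:.4f}", f"{r.d_drug:.4f}", r.degree,
          r.bin_index, r.rank] for r in ranked],
        out / "priorities.tsv",
        columns=["gene", "d_essential", "d_drug", "degree", "bin", "rank"])
    return ranked


def run_pipeline(cfg: dict, out_dir) -> dict:
    """Run every stage; returns the per-stage results for programmatic use."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    validate_config(cfg)
    _write_log(out, cfg)
    if cfg.get("inputs") is None:
        ppi, markers, table = stage_simulate(cfg, out)
    else:
        ppi, markers, table = load_inputs(cfg)
    assay_net = stage_project(table, cfg, out)
    topo = stage_topology(assay_net, out)
    enr = stage_enrich(ppi, markers, cfg, out)
    ranked = stage_prioritize(ppi, markers, cfg, out)
    return {"ppi": ppi, "markers": markers, "table": table,
            "assay_network": assay_net, "topology": topo,
            "enrichment": enr, "priorities": ranked}
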