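"""Synthetic screening data with planted, tunable network structure.

Three generators make the whole pipeline testable without external
databases:

* ``gen_ppi`` — a preferential-attachment (Barabási–Albert) interactome:
  connected, simple, heavy-tailed, with zero-padded synthetic gene symbols.
* ``gen_markers`` — marker sets planted on that interactome: essential
  genes drawn with degree-proportional bias (the empirical hub–lethality
  association), drug targets and disease genes drawn uniformly, and
  bioassay targets drawn with their sampling odds multiplied by
  ``proximity_rho`` when they lie within distance 1 of an essential gene.
  ``proximity_rho = 1`` is the exact uniform null; larger values plant the
  proximity enrichment the downstream analysis is meant to detect.
* ``gen_activity`` — a clustered bipartite activity table: assays and
  compounds are assigned to clusters and a pair is active with probability
  ``p_in`` within a cluster and ``p_out`` across, so the Jaccard
  projection of the result has community structure.

Every generator is a pure function of its arguments and seed: identical
seeds give bitwise-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .bipartite import ActivityTable, AssayInfo
from .neighborhood import MarkerSets


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic screen.

    Defaults are scaled to roughly one tenth of the data sizes the
    analysis is designed for (a ~20k-protein interactome with ~2.5k
    essential genes, ~1.3k drug targets and ~1.7k disease genes), with two
    deliberate departures from strict proportionality.  The bioassay-
    target count is kept at 60 (proportional would be ~22) so per-shell
    marker fractions remain estimable.  The essential-gene count is 60
    rather than ~240: essential genes are sampled degree-proportionally,
    and at this scale the distance-1 neighbourhood of a proportional
    essential set would blanket ~3/4 of a preferential-attachment graph,
    leaving the planted proximity signal nowhere to stand out; 60 keeps
    that neighbourhood near one third of the proteome, the regime in
    which planted enrichment is recoverable.
    """

    n_proteins: int = 2000
    attach_m: int = 3
    n_essential: int = 60
    n_drug_targets: int = 130
    n_disease: int = 170
    n_bioassay_targets: int = 60
    proximity_rho: float = 5.0
    n_assays: int = 60
    n_compounds: int = 600
    n_clusters: int = 6
    p_in: float = 0.30
    p_out: float = 0.005
    target_based_frac: float = 0.52
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "attach_m", "n_assays", "n_compounds",
                     "n_clusters"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("n_essential", "n_drug_targets", "n_disease",
                     "n_bioassay_targets"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_proteins <= self.attach_m:
            raise ConfigError("n_proteins must exceed attach_m")
        if self.n_essential + self.n_drug_targets > self.n_proteins:
            raise ConfigError("essential + drug-target counts exceed the proteome")
        if self.proximity_rho < 1:
            raise ConfigError("proximity_rho must be >= 1 (1 = uniform null)")
        for name in ("p_in", "p_out", "target_based_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability")
        if self.p_out > self.p_in:
            raise ConfigError("p_out must not exceed p_in")
        if self.n_clusters > self.n_assays:
            raise ConfigError("n_clusters must not exceed n_assays")


def _symbol(i: int) -> str:
    return f"G{i + 1:06d}"


def gen_ppi(n_proteins: int, attach_m: int, rng_seed: int) -> nx.Graph:
    """Preferential-attachment interactome with synthetic gene symbols.

    Connected simple undirected graph on ``n_proteins`` nodes with a
    heavy-tailed degree sequence; labels "G000001"… in attachment order.
    """
    if attach_m < 1 or n_proteins <= attach_m:
        raise ConfigError("need n_proteins > attach_m >= 1")
    g = nx.barabasi_albert_graph(n_proteins, attach_m, seed=rng_seed)
    return nx.relabel_nodes(g, {i: _symbol(i) for i in g})


def _weighted_sample_without_replacement(rng: np.random.Generator,
                                         items: Sequence[str],
                                         weights: np.ndarray,
                                         k: int) -> frozenset:
    """Efraimidis–Spirakis weighted reservoir keys: deterministic given rng."""
    if k == 0:
        return frozenset()
    if k > len(items):
        raise ConfigError(f"requested {k} items from a pool of {len(items)}")
    keys = rng.random(len(items)) ** (1.0 / weights)
    top = np.argsort(keys)[::-1][:k]
    return frozenset(items[i] for i in top)


def gen_markers(ppi: nx.Graph, cfg: SyntheticConfig,
                allow_overlap: bool = False) -> MarkerSets:
    """Plant marker sets on the interactome.

    Essential genes: degree-proportional sampling (hubs favoured).  Drug
    targets, disease genes: uniform.  Bioassay targets: odds multiplied by
    ``cfg.proximity_rho`` for proteins within distance 1 of an essential
    gene; drawn from the non-drug-target pool unless ``allow_overlap``.
    """
    nodes = sorted(ppi.nodes)
    if cfg.n_essential > len(nodes):
        raise ConfigError("n_essential exceeds the proteome")
    rng = np.random.default_rng([int(cfg.rng_seed), 1])

    degrees = np.array([ppi.degree(n) for n in nodes], dtype=float)
    essential = _weighted_sample_without_replacement(
        rng, nodes, np.maximum(degrees, 1e-12), cfg.n_essential)

    uniform = np.ones(len(nodes))
    drug = _weighted_sample_without_replacement(
        rng, nodes, uniform, cfg.n_drug_targets)
    disease = _weighted_sample_without_replacement(
        rng, nodes, uniform, cfg.n_disease)

    near_essential = set(essential)
    for e in essential:
        near_essential.update(ppi.neighbors(e))

    if allow_overlap:
        pool = nodes
    else:
        pool = [n for n in nodes if n not in drug]
    if cfg.n_bioassay_targets > len(pool):
        raise ConfigError("n_bioassay_targets exceeds the eligible pool")
    w = np.array([cfg.proximity_rho if n in near_essential else 1.0
                  for n in pool])
    bioassay = _weighted_sample_without_replacement(
        rng, pool, w, cfg.n_bioassay_targets)

    return MarkerSets(essential=essential, drug_targets=drug,
                      disease_genes=disease, bioassay_targets=bioassay)


def gen_activity(cfg: SyntheticConfig,
                 markers: Optional[MarkerSets] = None) -> ActivityTable:
    """Clustered bipartite activity table.

    Assays are assigned round-robin to ``n_clusters`` clusters and each
    compound gets a round-robin home cluster; pair (a, c) is active with
    probability ``p_in`` when they share a cluster, else ``p_out``.  A
    fraction ``target_based_frac`` of assays is marked target-based with a
    target symbol drawn from ``markers.bioassay_targets`` when markers are
    supplied; without markers every assay is cell-based.
    """
    rng = np.random.default_rng([int(cfg.rng_seed), 2])
    assay_ids = [f"A{i + 1:04d}" for i in range(cfg.n_assays)]
    compound_ids = [f"C{j + 1:06d}" for j in range(cfg.n_compounds)]
    assay_cluster = np.arange(cfg.n_assays) % cfg.n_clusters
    compound_cluster = np.arange(cfg.n_compounds) % cfg.n_clusters

    prob = np.where(
        assay_cluster[:, None] == compound_cluster[None, :], cfg.p_in, cfg.p_out)
    active = rng.random((cfg.n_assays, cfg.n_compounds)) < prob
    pairs = [(assay_ids[i], compound_ids[j])
             for i, j in zip(*np.nonzero(active))]

    targets = sorted(markers.bioassay_targets) if markers is not None else []
    is_target_based = (rng.random(cfg.n_assays) < cfg.target_based_frac) \
        if targets else np.zeros(cfg.n_assays, dtype=bool)
    meta: dict[str, AssayInfo] = {}
    for i, a in enumerate(assay_ids):
        if is_target_based[i]:
            symbol = targets[int(rng.integers(0, len(targets)))]
            meta[a] = AssayInfo("target_based", symbol)
        else:
            meta[a] = AssayInfo("cell_based")
    return ActivityTable(pairs=pairs, assay_meta=meta).validate()
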