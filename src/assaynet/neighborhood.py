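"""Marker-set neighbourhood analysis in a protein–protein interaction network.

Given a PPI network and named marker sets (essential genes, approved drug
targets, disease genes, bioassay targets), this module measures how a
marker set distributes over shortest-path shells around seed proteins and
whether that distribution is enriched relative to shells around randomly
chosen proteins.  The per-distance significance uses a two-sided Wilcoxon
rank-sum test between the per-seed and per-random-trial fraction samples.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats


@dataclass(frozen=True)
class MarkerSets:
    """Named node subsets of a PPI network."""

    essential: frozenset = frozenset()
    drug_targets: frozenset = frozenset()
    disease_genes: frozenset = frozenset()
    bioassay_targets: frozenset = frozenset()
    random_reference: Optional[frozenset] = None

    def as_dict(self) -> dict[str, frozenset]:
        d = {
            "essential": self.essential,
            "drug_targets": self.drug_targets,
            "disease_genes": self.disease_genes,
            "bioassay_targets": self.bioassay_targets,
        }
        if self.random_reference is not None:
            d["random_reference"] = self.random_reference
        return d


def map_symbols(symbols: Sequence[str], ppi: nx.Graph) -> tuple[set, list]:
    """Exact, case-sensitive match of symbols against PPI node labels.

    Returns (mapped node set, unmapped symbols in input order).  Unmapped
    symbols are reported, never silently dropped.
    """
    nodes = set(ppi.nodes)
    mapped = {s for s in symbols if s in nodes}
    unmapped = [s for s in symbols if s not in nodes]
    return mapped, unmapped


def bfs_distances(ppi: nx.Graph, source) -> dict:
    """Unweighted shortest-path distances from ``source``; unreachable
    nodes are absent from the result."""
    if source not in ppi:
        raise KeyError(f"source {source!r} not in the network")
    return dict(nx.single_source_shortest_path_length(ppi, source))


def fraction_profile(ppi: nx.Graph, seed, markers: Iterable) -> dict[int, float]:
    """Per-shell marker fractions around one seed.

    For each distance d >= 1 with at least one node, the fraction of those
    nodes that are markers.  The seed itself (d = 0) is excluded.
    """
    markers = set(markers)
    dist = bfs_distances(ppi, seed)
    totals: dict[int, int] = {}
    hits: dict[int, int] = {}
    for node, d in dist.items():
        if d == 0:
            continue
        totals[d] = totals.get(d, 0) + 1
        if node in markers:
            hits[d] = hits.get(d, 0) + 1
    return {d: hits.get(d, 0) / t for d, t in sorted(totals.items())}


class DistanceProfiler:
    """Caches per-node BFS distance arrays for repeated shell queries.

    The expensive part of the enrichment analysis is the breadth-first
    search from every seed and every random trial node; distances depend
    only on the graph, so they are computed once per node and reused
    across marker sets and replicates.
    """

    def __init__(self, ppi: nx.Graph):
        self.ppi = ppi
        self.nodes = sorted(ppi.nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self._dist: dict[int, np.ndarray] = {}

    def marker_mask(self, markers: Iterable) -> np.ndarray:
        mask = np.zeros(len(self.nodes), dtype=bool)
        for m in markers:
            i = self.index.get(m)
            if i is not None:
                mask[i] = True
        return mask

    def distances(self, node) -> np.ndarray:
        """int32 distance array indexed by node position; −1 = unreachable."""
        i = self.index[node]
        arr = self._dist.get(i)
        if arr is None:
            arr = np.full(len(self.nodes), -1, dtype=np.int32)
            for n, d in nx.single_source_shortest_path_length(self.ppi, node).items():
                arr[self.index[n]] = d
            self._dist[i] = arr
        return arr

    def shell_counts(self, node, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(total nodes, marker nodes) per distance 1..max around ``node``."""
        dist = self.distances(node)
        reach = dist > 0
        totals = np.bincount(dist[reach])
        hits = np.bincount(dist[reach & mask], minlength=len(totals))
        return totals, hits


@dataclass(frozen=True)
class EnrichmentResult:
    distances: list[int]
    mean_fraction: dict[int, float]
    random_mean_fraction: dict[int, float]
    p_value: dict[int, float]
    n_seeds: int
    n_random: int


def enrichment(ppi: nx.Graph, seeds: Iterable, markers: Iterable,
               n_random: int = 10000, rng_seed: Optional[int] = None,
               profiler: Optional[DistanceProfiler] = None) -> EnrichmentResult:
    """Distance-profile enrichment of ``markers`` around ``seeds``.

    For every distance d, the mean over seeds of the shell-d marker
    fraction is compared with the same quantity over ``n_random`` uniform
    draws (with replacement) of a protein; the per-distance p-value is a
    two-sided rank-sum test of the two fraction samples.  Seeds (or random
    trials) with no node at distance d are skipped at that d.
    """
    seeds = sorted(set(seeds))
    marker_set = set(markers)
    if not seeds:
        raise ValueError("seeds must be nonempty")
    if not marker_set:
        raise ValueError("markers must be nonempty")
    prof = profiler if profiler is not None else DistanceProfiler(ppi)
    if prof.ppi is not ppi:
        raise ValueError("profiler was built for a different network")
    mask = prof.marker_mask(marker_set)

    rng = np.random.default_rng(rng_seed)
    random_nodes = [prof.nodes[i]
                    for i in rng.integers(0, len(prof.nodes), size=n_random)]

    def collect(anchor_nodes):
        per = []
        for node in anchor_nodes:
            totals, hits = prof.shell_counts(node, mask)
            per.append((totals, hits))
        return per

    seed_shells = collect(seeds)
    rand_shells = collect(random_nodes)

    d_max = max((len(t) - 1 for t, _ in seed_shells), default=0)
    distances, mean_f, rand_f, pvals = [], {}, {}, {}
    for d in range(1, d_max + 1):
        xs = [h[d] / t[d] for t, h in seed_shells if len(t) > d and t[d] > 0]
        ys = [h[d] / t[d] for t, h in rand_shells if len(t) > d and t[d] > 0]
        if not xs:
            continue
        distances.append(d)
        mean_f[d] = float(np.mean(xs))
        rand_f[d] = float(np.mean(ys)) if ys else math.nan
        pvals[d] = ranksum(xs, ys) if ys else math.nan
    return EnrichmentResult(
        distances=distances, mean_fraction=mean_f,
        random_mean_fraction=rand_f, p_value=pvals,
        n_seeds=len(seeds), n_random=n_random,
    )


def degree_cdf(ppi: nx.Graph, node_set: Iterable,
               k_range: range = range(1, 52)) -> dict[int, float]:
    """Percentage of set members with degree >= k, for k in ``k_range``.

    The curve is non-increasing; its value at k=1 is the percentage of
    non-isolated members.
    """
    members = set(node_set)
    if not members:
        raise ValueError("node_set must be nonempty")
    unknown = members - set(ppi.nodes)
    if unknown:
        raise KeyError(f"{len(unknown)} members not in the network")
    degrees = np.array([ppi.degree(n) for n in members])
    return {k: float((degrees >= k).mean() * 100.0) for k in k_range}


def ranksum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum test for equal medians.

    Exact enumeration of the rank-sum null distribution when the pooled
    sample has at most 10 observations and no ties; otherwise the normal
    approximation with tie correction and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    total = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())

    if total <= 10 and np.unique(pooled).size == total:
        sums = np.fromiter(
            (sum(c) for c in itertools.combinations(range(1, total + 1), n1)),
            dtype=float,
        )
        p = 2.0 * min((sums <= w).mean(), (sums >= w).mean())
        return float(min(p, 1.0))

    mu = n1 * (total + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    var = n1 * n2 / 12.0 * ((total + 1) - tie_term / (total * (total - 1)))
    if var <= 0:
        return 1.0  # all observations tied
    diff = w - mu
    diff = math.copysign(max(abs(diff) - 0.5, 0.0), diff) if diff != 0 else 0.0
    z = diff / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))
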