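"""Jaccard projection of the bipartite activity network onto assays.

Two assays are connected when the Jaccard coefficient of their active
compound sets — |shared actives| / |distinct actives of either| — meets a
threshold (default 0.10, i.e. "share at least 10% active compounds").
The projection uses an inverted compound→assays index so only assay pairs
that actually share a compound are scored; the result is identical to the
all-pairs computation.
"""

from __future__ import annotations

from collections import defaultdict
from typing import AbstractSet

import networkx as nx

from .bipartite import BipartiteNet

#: tolerance for the inclusive threshold comparison, so that e.g. an
#: intersection/union ratio of exactly 10% passes regardless of binary
#: floating-point representation.
_EPS = 1e-12


def jaccard(a: AbstractSet, b: AbstractSet) -> float:
    """|a ∩ b| / |a ∪ b|.  Undefined (raises) when both sets are empty."""
    union = len(a | b)
    if union == 0:
        raise ValueError("Jaccard coefficient of two empty sets is undefined (0/0)")
    return len(a & b) / union


def project(net: BipartiteNet, min_jaccard: float = 0.10,
            drop_isolates: bool = False) -> nx.Graph:
    """Weighted assay–assay projection.

    Nodes are the assays of ``net`` (each has >=1 active compound by
    construction); an edge joins two assays whose active-compound Jaccard
    coefficient is >= ``min_jaccard`` (inclusive), with the coefficient
    stored as edge attribute ``jaccard``.  Assay metadata and the active
    compound count are copied onto the nodes.  Isolated assays are kept by
    default so the node count reflects the full assay population.
    """
    if not 0.0 < min_jaccard <= 1.0:
        raise ValueError("min_jaccard must be in (0, 1]")

    g = net.graph
    assay_sets: dict[str, set] = {
        a: set(g.neighbors(a)) for a in net.assay_nodes
    }

    proj = nx.Graph()
    for a, compounds in assay_sets.items():
        proj.add_node(
            a,
            assay_type=g.nodes[a].get("assay_type"),
            target_symbol=g.nodes[a].get("target_symbol"),
            n_active_compounds=len(compounds),
        )

    # inverted index: compound -> assays it is active in
    by_compound: dict[str, list[str]] = defaultdict(list)
    for a, compounds in assay_sets.items():
        for c in compounds:
            by_compound[c].append(a)

    inter: dict[tuple[str, str], int] = defaultdict(int)
    for assays in by_compound.values():
        assays = sorted(assays)
        for i, u in enumerate(assays):
            for v in assays[i + 1:]:
                inter[(u, v)] += 1

    for (u, v), shared in inter.items():
        union = len(assay_sets[u]) + len(assay_sets[v]) - shared
        j = shared / union
        if j + _EPS >= min_jaccard:
            proj.add_edge(u, v, jaccard=j)

    if drop_isolates:
        proj.remove_nodes_from([n for n in proj if proj.degree(n) == 0])
    return proj
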