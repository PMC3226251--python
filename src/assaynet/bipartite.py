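"""Bioassay–compound bipartite network construction and summaries.

The screening data are modelled as a bipartite graph: one partition holds
bioassays (high-throughput screens), the other holds compounds that were
flagged active in at least one screen.  An edge means "this compound is
active in this assay".  The module builds that graph from an activity
table, reports the sparsity summaries (mean active compounds per assay,
mean active assays per compound), and extracts degree-window subnetworks
for visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

ASSAY_TYPES = ("target_based", "cell_based")


@dataclass(frozen=True)
class AssayInfo:
    """Metadata for one bioassay: screen type and, for target-based
    screens, the gene symbol of the protein it was run against."""

    assay_type: str
    target_symbol: Optional[str] = None

    def __post_init__(self) -> None:
        if self.assay_type not in ASSAY_TYPES:
            raise ValueError(f"unknown assay_type {self.assay_type!r}")
        if self.target_symbol is not None and self.assay_type != "target_based":
            raise ValueError(
                f"target_symbol set on a {self.assay_type} assay; only "
                "target_based assays carry a target"
            )


@dataclass
class ActivityTable:
    """Active (assay, compound) pairs plus per-assay metadata.

    Invariants: no duplicate pairs; every pair's assay_id has metadata.
    """

    pairs: list[tuple[str, str]]
    assay_meta: dict[str, AssayInfo] = field(default_factory=dict)

    def validate(self) -> "ActivityTable":
        seen: set[tuple[str, str]] = set()
        for p in self.pairs:
            if p in seen:
                raise ValueError(f"duplicate activity pair {p}")
            seen.add(p)
        missing = {a for a, _ in self.pairs} - set(self.assay_meta)
        if missing:
            raise ValueError(
                f"{len(missing)} assay ids lack metadata, e.g. {sorted(missing)[:3]}"
            )
        return self

    @property
    def assay_ids(self) -> set[str]:
        return set(self.assay_meta)


class BipartiteNet:
    """Two-coloured undirected graph of assays and compounds.

    Thin wrapper over a networkx Graph whose nodes carry a ``bipartite``
    attribute in {"assay", "compound"}.
    """

    def __init__(self, graph: Optional[nx.Graph] = None):
        self.graph = graph if graph is not None else nx.Graph()

    @property
    def assay_nodes(self) -> set[str]:
        return {n for n, side in self.graph.nodes(data="bipartite") if side == "assay"}

    @property
    def compound_nodes(self) -> set[str]:
        return {n for n, side in self.graph.nodes(data="bipartite") if side == "compound"}

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Edges oriented (assay, compound)."""
        out = set()
        for u, v in self.graph.edges():
            if self.graph.nodes[u]["bipartite"] == "assay":
                out.add((u, v))
            else:
                out.add((v, u))
        return out

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass(frozen=True)
class BipartiteSummary:
    n_assays_active: int
    n_active_compounds: int
    n_pairs: int
    mean_compounds_per_assay: float
    mean_assays_per_compound: float


def build_bipartite(table: ActivityTable) -> BipartiteNet:
    """Build the bipartite activity network from a validated table.

    One node per distinct assay with >=1 active compound, one per distinct
    active compound, one edge per pair.  Assays listed in the metadata but
    with no active compound do not appear as nodes.  Assay node attributes
    carry the metadata so projections and exports can reuse it.
    """
    table.validate()
    assays = {a for a, _ in table.pairs}
    compounds = {c for _, c in table.pairs}
    clash = assays & compounds
    if clash:
        raise ValueError(f"ids used both as assay and compound: {sorted(clash)[:3]}")
    g = nx.Graph()
    for a in assays:
        info = table.assay_meta[a]
        g.add_node(a, bipartite="assay", assay_type=info.assay_type,
                   target_symbol=info.target_symbol)
    for c in compounds:
        g.add_node(c, bipartite="compound")
    g.add_edges_from(table.pairs)
    return BipartiteNet(g)


def to_pairs(net: BipartiteNet) -> set[tuple[str, str]]:
    """Decompose the network back into its (assay, compound) pair set."""
    return net.edges


def summarize(net: BipartiteNet) -> BipartiteSummary:
    """Counts and the two sparsity means.

    Raises on an empty network — the means are undefined there.
    """
    n_pairs = net.graph.number_of_edges()
    n_assays = len(net.assay_nodes)
    n_compounds = len(net.compound_nodes)
    if n_assays == 0 or n_compounds == 0:
        raise ValueError("summary undefined on an empty bipartite network")
    return summary_from_counts(n_pairs, n_assays, n_compounds)


def summary_from_counts(n_pairs: int, n_assays_active: int,
                        n_active_compounds: int) -> BipartiteSummary:
    """Summary from pre-tabulated totals (e.g. published screen counts)."""
    if n_assays_active <= 0 or n_active_compounds <= 0:
        raise ValueError("counts must be positive")
    return BipartiteSummary(
        n_assays_active=n_assays_active,
        n_active_compounds=n_active_compounds,
        n_pairs=n_pairs,
        mean_compounds_per_assay=n_pairs / n_assays_active,
        mean_assays_per_compound=n_pairs / n_active_compounds,
    )


def extract_subnetwork(net: BipartiteNet,
                       assay_deg: tuple[int, int],
                       compound_deg: tuple[int, int],
                       iterate: bool = False) -> BipartiteNet:
    """Degree-window subnetwork for visualisation.

    Keeps assay nodes whose degree (in the input network) lies in the
    inclusive window ``assay_deg`` and compound nodes in ``compound_deg``,
    then keeps edges with both endpoints surviving and drops nodes left
    isolated.  With ``iterate=True`` the filter is re-applied on the
    shrinking network until a fixed point (degrees re-measured each pass).
    """
    for lo, hi in (assay_deg, compound_deg):
        if lo > hi:
            raise ValueError(f"degree window [{lo},{hi}] has lo > hi")

    def one_pass(g: nx.Graph) -> nx.Graph:
        keep = []
        for n, side in g.nodes(data="bipartite"):
            lo, hi = assay_deg if side == "assay" else compound_deg
            if lo <= g.degree(n) <= hi:
                keep.append(n)
        sub = g.subgraph(keep).copy()
        sub.remove_nodes_from([n for n in sub if sub.degree(n) == 0])
        return sub

    g = net.graph
    out = one_pass(g)
    if iterate:
        while out.number_of_nodes() != g.number_of_nodes():
            g, out = out, one_pass(out)
    return BipartiteNet(out)
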