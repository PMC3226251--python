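"""TSV / GraphML readers and writers.

Formats:

* ``activity.tsv``   — header ``assay_id\tcompound_id``, one active pair per row.
* ``assays.tsv``     — header ``assay_id\tassay_type\ttarget_symbol`` (symbol may be empty).
* ``ppi_edges.tsv``  — two gene symbols per row, '#' comment lines allowed.
* marker files       — one gene symbol per line.
* result tables      — TSV with header, written via pandas.
* networks           — GraphML with typed node/edge attributes (Cytoscape-loadable).

Every dropped record (duplicate edge, self-loop) is counted and logged;
malformed rows raise a ``ParseError`` naming the offending line.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import networkx as nx
import pandas as pd

from .bipartite import ASSAY_TYPES, ActivityTable, AssayInfo

log = logging.getLogger("assaynet")

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input file; the message names the file and line."""


def _rows(path: PathLike, n_fields: int, header: Sequence[str] | None):
    """Yield (line_number, fields) from a TSV, enforcing field count."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is not None and lineno == 1:
                if [f.strip() for f in fields] != list(header):
                    raise ParseError(
                        f"{path}:{lineno}: expected header "
                        f"{chr(9).join(header)!r}, got {line!r}")
                continue
            if len(fields) != n_fields:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_fields} tab-separated "
                    f"fields, got {len(fields)}")
            yield lineno, [f.strip() for f in fields]


def read_activity(activity_path: PathLike, meta_path: PathLike) -> ActivityTable:
    """Read the active-pair table and assay metadata, validating both."""
    meta: dict[str, AssayInfo] = {}
    for lineno, (assay, atype, symbol) in _rows(
            meta_path, 3, header=("assay_id", "assay_type", "target_symbol")):
        if atype not in ASSAY_TYPES:
            raise ParseError(
                f"{meta_path}:{lineno}: unknown assay_type {atype!r}")
        if assay in meta:
            raise ParseError(f"{meta_path}:{lineno}: duplicate assay {assay!r}")
        try:
            meta[assay] = AssayInfo(atype, symbol or None)
        except ValueError as exc:
            raise ParseError(f"{meta_path}:{lineno}: {exc}") from exc

    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for lineno, (assay, compound) in _rows(
            activity_path, 2, header=("assay_id", "compound_id")):
        pair = (assay, compound)
        if pair in seen:
            raise ParseError(
                f"{activity_path}:{lineno}: duplicate pair {pair}")
        if assay not in meta:
            raise ParseError(
                f"{activity_path}:{lineno}: assay {assay!r} missing from metadata")
        seen.add(pair)
        pairs.append(pair)
    return ActivityTable(pairs=pairs, assay_meta=meta).validate()


def write_activity(table: ActivityTable, activity_path: PathLike,
                   meta_path: PathLike) -> None:
    with Path(activity_path).open("w", encoding="utf-8") as fh:
        fh.write("assay_id\tcompound_id\n")
        for a, c in table.pairs:
            fh.write(f"{a}\t{c}\n")
    with Path(meta_path).open("w", encoding="utf-8") as fh:
        fh.write("assay_id\tassay_type\ttarget_symbol\n")
        for a in sorted(table.assay_meta):
            info = table.assay_meta[a]
            fh.write(f"{a}\t{info.assay_type}\t{info.target_symbol or ''}\n")


def read_edges(path: PathLike) -> nx.Graph:
    """Undirected simple graph from a two-column symbol edge list.

    Self-loops and duplicate edges (in either orientation) are dropped
    with a logged count; an empty file yields an empty graph and a warning.
    """
    g = nx.Graph()
    n_self, n_dup = 0, 0
    for lineno, (u, v) in _rows(path, 2, header=None):
        if u == v:
            n_self += 1
            continue
        if g.has_edge(u, v):
            n_dup += 1
            continue
        g.add_edge(u, v)
    if n_self:
        log.warning("%s: dropped %d self-loop rows", path, n_self)
    if n_dup:
        log.warning("%s: dropped %d duplicate edge rows", path, n_dup)
    if g.number_of_edges() == 0:
        log.warning("%s: no edges read", path)
    return g


def write_edges(graph: nx.Graph, path: PathLike) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{u}\t{v}\n")


def read_markers(path: PathLike) -> list[str]:
    """One gene symbol per line; order preserved, comments skipped."""
    out: list[str] = []
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_markers(symbols: Iterable[str], path: PathLike) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in sorted(symbols):
            fh.write(f"{s}\n")


def write_graphml(graph: nx.Graph, path: PathLike) -> None:
    """GraphML export; None attributes are serialised as empty strings."""
    g = graph.copy()
    for _, data in g.nodes(data=True):
        for k, v in list(data.items()):
            if v is None:
                data[k] = ""
    nx.write_graphml(g, str(path))


def read_graphml(path: PathLike) -> nx.Graph:
    g = nx.read_graphml(str(path))
    return nx.Graph(g)


def write_table(rows, path: PathLike,
                columns: Sequence[str] | None = None) -> None:
    """Result table as TSV with header; byte-stable for identical input."""
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows), columns=columns)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
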