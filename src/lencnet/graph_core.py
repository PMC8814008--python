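"""Graph container, edge-list I/O, and structural primitives.

Networks are plain :class:`networkx.Graph` objects holding undirected
simple graphs.  Node identifiers are opaque strings: numeric-looking ids
are never coerced, so a file written with ids ``"007"`` and ``"7"`` keeps
them distinct.  Insertion order of nodes is preserved by networkx, which
makes every iteration in this package reproducible.

The reader accepts the common plain edge-list dialect: two id columns per
line, ``#`` comments and blank lines ignored, delimiter auto-detected
among comma / tab / whitespace.  Self-loops are dropped and duplicate
edges collapsed (the methods downstream assume simple graphs); the counts
of both are logged at DEBUG level.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

#: Alias used in signatures throughout the package.
Graph = nx.Graph


class EdgeListParseError(ValueError):
    """Raised when an edge-list line cannot be split into two node ids."""


def _iter_lines(source: str | Path) -> Iterable[str]:
    if isinstance(source, Path):
        return source.read_text().splitlines()
    if isinstance(source, str):
        # A short string with no newline that names an existing file is a
        # path; anything else is treated as literal edge-list text.
        if "\n" not in source and os.path.exists(source):
            return Path(source).read_text().splitlines()
        return source.splitlines()
    raise TypeError(f"source must be str or Path, got {type(source)!r}")


def _split(line: str, delimiter: str | None) -> list[str]:
    if delimiter is not None:
        return [t for t in line.split(delimiter) if t.strip() != ""]
    if "," in line:
        return [t.strip() for t in line.split(",") if t.strip() != ""]
    return line.split()


def read_edge_list(source: str | Path, delimiter: str | None = None) -> nx.Graph:
    """Parse a two-column edge list into an undirected simple graph.

    Parameters
    ----------
    source:
        Path to a file, or the edge-list text itself.
    delimiter:
        Column separator.  When ``None`` the delimiter is auto-detected
        per line (comma if present, otherwise any whitespace).

    Raises
    ------
    EdgeListParseError
        If a non-comment line has exactly one token, or the input
        contains no usable lines at all.
    """
    g = nx.Graph()
    n_loops = 0
    n_dups = 0
    seen_any = False
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = _split(line, delimiter)
        if len(tokens) < 2:
            raise EdgeListParseError(
                f"line {lineno}: expected two node ids, got {len(tokens)}: {raw!r}"
            )
        seen_any = True
        u, v = str(tokens[0]), str(tokens[1])
        if u == v:
            n_loops += 1
            g.add_node(u)
            continue
        if g.has_edge(u, v):
            n_dups += 1
            continue
        g.add_edge(u, v)
    if not seen_any:
        raise EdgeListParseError("empty edge list: no non-comment lines found")
    if n_loops or n_dups:
        logger.debug(
            "read_edge_list: dropped %d self-loop(s), collapsed %d duplicate edge(s)",
            n_loops,
            n_dups,
        )
    return g


def write_edge_list(g: nx.Graph, path: str | Path, delimiter: str = " ") -> None:
    """Write ``g`` as a plain two-column edge list (round-trips with the reader)."""
    with open(path, "w") as fh:
        for u, v in g.edges():
            fh.write(f"{u}{delimiter}{v}\n")


def degree(g: nx.Graph, v) -> int:
    """Degree of ``v`` in the real graph (never counts virtual edges)."""
    if v not in g:
        raise KeyError(f"unknown node: {v!r}")
    return g.degree(v)


def common_neighbor_count(g: nx.Graph, m, n) -> int:
    """Number of common neighbors of ``m`` and ``n``.

    For an edge (m, n) this equals the number of triangles the edge sits
    in.  Symmetric in its arguments; undefined (raises) for ``m == n``.
    """
    if m == n:
        raise ValueError("common_neighbor_count is undefined for a node with itself")
    if m not in g:
        raise KeyError(f"unknown node: {m!r}")
    if n not in g:
        raise KeyError(f"unknown node: {n!r}")
    return len(set(g[m]) & set(g[n]))


def k_shell(g: nx.Graph) -> dict:
    """K-shell (core-number) index of every node.

    Standard iterative peeling: repeatedly remove all nodes of degree
    <= k and assign them shell index k, for k = 0, 1, 2, ...  Isolated
    nodes get shell 0.
    """
    return dict(nx.core_number(g))


def connected_components(g: nx.Graph) -> list[set]:
    """Partition of the node set into maximal connected components."""
    return [set(c) for c in nx.connected_components(g)]


def mean_degree_moments(g: nx.Graph) -> tuple[float, float]:
    """First and second moments (⟨k⟩, ⟨k²⟩) of the degree distribution."""
    if g.number_of_nodes() == 0:
        raise ValueError("mean_degree_moments undefined on an empty graph")
    degs = [d for _, d in g.degree()]
    n = len(degs)
    return sum(degs) / n, sum(d * d for d in degs) / n
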