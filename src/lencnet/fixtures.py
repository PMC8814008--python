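"""Bundled reference networks and seeded synthetic generators.

Two small classic networks ship with the package as plain edge lists so
every experiment and test runs offline: a 6-node toy network whose LENC
intermediates are all known in closed form, and the Zachary karate club
network (34 nodes, 78 edges).  The random-graph generators wrap the
standard networkx constructions with explicit seeds and string node ids.
"""

from __future__ import annotations

from importlib import resources

import networkx as nx

from .graph_core import read_edge_list


def _load_bundled(name: str) -> nx.Graph:
    text = resources.files("lencnet.data").joinpath(name).read_text()
    return read_edge_list(text)


def toy_network() -> nx.Graph:
    """The 6-node, 7-edge example network of the worked golden tests.

    Edges {1–2, 2–3, 2–4, 3–4, 3–6, 4–5, 4–6}; degrees (1, 3, 3, 4, 1, 2)
    for nodes 1…6.  Node 4 is the hub whose every LENC intermediate
    (virtual weight 9.6, total weight 16.9904, entropy 1.76105, final
    influence 12.8902, …) is pinned by the test suite.
    """
    return _load_bundled("toy.edges")


def karate_network() -> nx.Graph:
    """Zachary's karate club, 1-based node ids (34 nodes, 78 edges)."""
    return _load_bundled("karate.edges")


def _relabel(g: nx.Graph) -> nx.Graph:
    return nx.relabel_nodes(g, {v: str(v) for v in g.nodes()})


def generate_er(n: int, p: float, seed: int) -> nx.Graph:
    """Erdős–Rényi G(n, p) with string node ids, reproducible per seed."""
    if n < 0 or not 0.0 <= p <= 1.0:
        raise ValueError("need n >= 0 and p in [0, 1]")
    return _relabel(nx.gnp_random_graph(n, p, seed=seed))


def generate_ba(n: int, m: int, seed: int) -> nx.Graph:
    """Barabási–Albert preferential attachment: m edges per new node."""
    if not 1 <= m < n:
        raise ValueError(f"need 1 <= m < n, got m={m}, n={n}")
    return _relabel(nx.barabasi_albert_graph(n, m, seed=seed))


def generate_ws(n: int, k: int, p: float, seed: int) -> nx.Graph:
    """Watts–Strogatz ring lattice (k nearest neighbors) rewired with prob. p."""
    if k >= n or not 0.0 <= p <= 1.0:
        raise ValueError("need k < n and p in [0, 1]")
    return _relabel(nx.watts_strogatz_graph(n, k, p, seed=seed))
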