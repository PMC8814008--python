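"""Comparison centralities: CC, EC, HITS, H-index, DIL, degree, k-shell.

All return a :class:`~lencnet.lenc.ScoreTable` so that rankings from any
method can be fed to the same SIR / Kendall evaluation machinery.
Standard measures (closeness, eigenvector, HITS) delegate to networkx;
H-index and DIL are implemented here.
"""

from __future__ import annotations

import networkx as nx

from .graph_core import common_neighbor_count, k_shell
from .lenc import ScoreTable


def closeness_centrality(g: nx.Graph) -> ScoreTable:
    """Closeness centrality, Wasserman–Faust scaled on disconnected graphs.

    Per node, (n_c − 1) / Σ d(v, u) over its component of size n_c,
    multiplied by (n_c − 1)/(|V| − 1).  Singleton components score 0.
    """
    return ScoreTable(dict(nx.closeness_centrality(g, wf_improved=True)))


def eigenvector_centrality(g: nx.Graph, tol: float = 1e-10, max_iter: int = 1000) -> ScoreTable:
    """Principal-eigenvector centrality via power iteration (L2-normalized)."""
    try:
        scores = nx.eigenvector_centrality(g, tol=tol, max_iter=max_iter)
    except nx.PowerIterationFailedConvergence as exc:
        raise RuntimeError(
            f"eigenvector centrality did not converge within {max_iter} iterations"
        ) from exc
    return ScoreTable(dict(scores))


def hits_scores(g: nx.Graph, tol: float = 1e-10, max_iter: int = 1000) -> ScoreTable:
    """HITS authority scores.

    On an undirected graph the adjacency matrix is symmetric, so hub and
    authority vectors coincide and equal the principal eigenvector up to
    normalization; authorities are reported.
    """
    try:
        _, authorities = nx.hits(g, tol=tol, max_iter=max_iter)
    except nx.PowerIterationFailedConvergence as exc:
        raise RuntimeError(
            f"HITS did not converge within {max_iter} iterations"
        ) from exc
    return ScoreTable(dict(authorities))


def hindex_centrality(g: nx.Graph) -> ScoreTable:
    """H-index of each node: the largest h with ≥ h neighbors of degree ≥ h."""
    scores = {}
    for v in g.nodes():
        nbr_degs = sorted((g.degree(u) for u in g[v]), reverse=True)
        h = 0
        for i, d in enumerate(nbr_degs, start=1):
            if d >= i:
                h = i
            else:
                break
        scores[v] = float(h)
    return ScoreTable(scores)


def dil_scores(g: nx.Graph) -> ScoreTable:
    """DIL: degree plus importance-of-lines contributions.

    DIL(i) = k_i + Σ_{j∈Γ(i)} I_ij · (k_i − 1)/(k_i + k_j − 2), where the
    line importance I_ij = U/λ with U = (k_i − p − 1)(k_j − p − 1),
    λ = p/2 + 1 and p the number of triangles on edge (i, j).  An edge
    between two degree-1 nodes (k_i + k_j = 2) contributes 0.
    """
    deg = dict(g.degree())
    scores = {}
    for i in g.nodes():
        ki = deg[i]
        acc = float(ki)
        for j in g[i]:
            kj = deg[j]
            if ki + kj == 2:
                continue
            p = common_neighbor_count(g, i, j)
            u = (ki - p - 1) * (kj - p - 1)
            lam = p / 2 + 1
            acc += (u / lam) * (ki - 1) / (ki + kj - 2)
        scores[i] = acc
    return ScoreTable(scores)


def degree_centrality(g: nx.Graph) -> ScoreTable:
    """Raw degree as a score."""
    return ScoreTable({v: float(d) for v, d in g.degree()})


def k_shell_centrality(g: nx.Graph) -> ScoreTable:
    """K-shell (core-number) index as a score."""
    return ScoreTable({v: float(c) for v, c in k_shell(g).items()})
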