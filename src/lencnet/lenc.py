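"""The LENC centrality: local-structure entropy node ranking.

The score of a node combines three local ingredients:

1. *Triangle-adjusted asymmetric edge weights.*  For an edge (m, n) with
   triangle count T_mn = |Γ(m) ∩ Γ(n)|,

       W_mn = (k_m − T_mn)(k_n − T_mn) · R_mn · w_mn / (T_mn/2 + 1),
       R_mn = k_m / (k_m + k_n),

   with the intrinsic edge weight w_mn fixed to 1.  The contribution
   coefficient R makes the weight direction-dependent: W_mn ≠ W_nm in
   general, so the same edge contributes differently to its two ends.

2. *A virtual node.*  An auxiliary node v' of degree N (the number of
   real nodes) is connected to every node, contributing

       W_mv' = k_m² · N / (k_m + N)

   (the edge formula with T = 0 and partner degree N).  Without it every
   leaf would have zero edge-weight entropy and structurally similar
   nodes attached to different hubs would be indistinguishable.  The
   virtual node is pure bookkeeping: it never enters the graph and never
   alters any degree.

3. *Entropy × coreness, aggregated over two orders.*  The weight
   fractions p = W/W_m over a node's (virtual + real) edges form a
   probability distribution; its Shannon entropy (base 2) times the
   node's k-shell index gives the local influence, and the final score
   adds the local influences of the node's neighbors:

       Influence(m) = influence(m) + Σ_{n ∈ Γ(m)} influence(n).

Only first- and second-order terms are aggregated; no higher-order
extension is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .graph_core import common_neighbor_count, k_shell


@dataclass
class ScoreTable:
    """Node scores with a deterministic 1-based ranking.

    Ranks sort by descending score; ties are broken by ascending node id
    (string order), so output is reproducible across runs and platforms.
    """

    score: dict
    rank: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.rank:
            ordered = sorted(self.score, key=lambda v: (-self.score[v], str(v)))
            self.rank = {v: i + 1 for i, v in enumerate(ordered)}

    def top(self, k: int) -> list:
        """The ``k`` highest-ranked nodes, best first."""
        if k > len(self.score):
            raise ValueError(f"k={k} exceeds number of nodes {len(self.score)}")
        ordered = sorted(self.rank, key=self.rank.get)
        return ordered[:k]

    def to_frame(self) -> pd.DataFrame:
        ordered = sorted(self.rank, key=self.rank.get)
        return pd.DataFrame(
            {
                "node": ordered,
                "score": [self.score[v] for v in ordered],
                "rank": [self.rank[v] for v in ordered],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df["score"] = df["score"].map(lambda x: f"{x:.6f}")
        df.to_csv(path, index=False)


@dataclass
class EdgeInfluenceTable:
    """All intermediate quantities of the entropy construction.

    ``directed_weight[(m, n)]`` is W_mn for every ordered adjacent pair;
    ``virtual_weight[m]`` is W_mv'; ``total_weight[m]`` is W_m;
    ``edge_entropy`` / ``virtual_entropy`` hold the −p·log₂p terms.
    """

    directed_weight: dict
    virtual_weight: dict
    total_weight: dict
    edge_entropy: dict
    virtual_entropy: dict


def _plogp(p: float) -> float:
    # 0·log 0 := 0 (defensive; p = 0 cannot arise for real edges of a
    # simple graph since T_mn <= min(k_m, k_n) - 1).
    if p <= 0.0:
        return 0.0
    return -p * math.log2(p)


def edge_weight(g: nx.Graph, m, n, w_mn: float = 1.0) -> float:
    """Directed weight W_mn of edge (m, n) as seen from ``m``.

    ``w_mn`` is the intrinsic edge weight hook; it defaults to 1 and is
    the only place a weighted-network variant would plug in.
    """
    if not g.has_edge(m, n):
        raise ValueError(f"({m!r}, {n!r}) is not an edge")
    km = g.degree(m)
    kn = g.degree(n)
    t = common_neighbor_count(g, m, n)
    r = km / (km + kn)
    return (km - t) * (kn - t) * r * w_mn / (t / 2 + 1)


def virtual_edge_weight(g: nx.Graph, m) -> float:
    """Weight W_mv' of the edge from ``m`` to the virtual node.

    The virtual node has degree N = |V| (real nodes only) and shares no
    triangles with anyone, so W_mv' = k_m² N / (k_m + N).  Returns 0 for
    an isolated node.
    """
    if m not in g:
        raise KeyError(f"unknown node: {m!r}")
    k = g.degree(m)
    if k == 0:
        return 0.0
    n = g.number_of_nodes()
    return k * k * n / (k + n)


def node_total_weight(g: nx.Graph, m) -> float:
    """W_m: virtual-edge weight plus all first-order directed weights."""
    return virtual_edge_weight(g, m) + sum(edge_weight(g, m, n) for n in g[m])


def edge_entropy_terms(g: nx.Graph, m) -> tuple[float, dict]:
    """Per-edge entropy terms of node ``m``: (virtual term, {neighbor: term}).

    Each term is −p·log₂p with p the corresponding weight fraction
    W/W_m.  For an isolated node (W_m = 0) every term is 0.
    """
    total = node_total_weight(g, m)
    if total == 0.0:
        return 0.0, {}
    virt = _plogp(virtual_edge_weight(g, m) / total)
    terms = {n: _plogp(edge_weight(g, m, n) / total) for n in g[m]}
    return virt, terms


def node_entropy(g: nx.Graph, m) -> float:
    """First-order edge entropy of ``m`` (virtual + neighbor terms, bits)."""
    virt, terms = edge_entropy_terms(g, m)
    return virt + sum(terms.values())


def local_influence(g: nx.Graph, cores: dict, m) -> float:
    """Local influence: node entropy scaled by the k-shell position index."""
    return node_entropy(g, m) * cores[m]


def edge_influence_table(g: nx.Graph) -> EdgeInfluenceTable:
    """Compute every weight and entropy term of the construction at once."""
    n_nodes = g.number_of_nodes()
    deg = dict(g.degree())
    directed_weight = {}
    virtual_weight = {}
    total_weight = {}
    for m in g.nodes():
        km = deg[m]
        virtual_weight[m] = 0.0 if km == 0 else km * km * n_nodes / (km + n_nodes)
        acc = virtual_weight[m]
        adj_m = set(g[m])
        for n in g[m]:
            t = len(adj_m & set(g[n]))
            w = (km - t) * (deg[n] - t) * (km / (km + deg[n])) / (t / 2 + 1)
            directed_weight[(m, n)] = w
            acc += w
        total_weight[m] = acc
    edge_entropy = {}
    virtual_entropy = {}
    for m in g.nodes():
        total = total_weight[m]
        if total == 0.0:
            virtual_entropy[m] = 0.0
            continue
        virtual_entropy[m] = _plogp(virtual_weight[m] / total)
        for n in g[m]:
            edge_entropy[(m, n)] = _plogp(directed_weight[(m, n)] / total)
    return EdgeInfluenceTable(
        directed_weight, virtual_weight, total_weight, edge_entropy, virtual_entropy
    )


def lenc_scores(g: nx.Graph) -> ScoreTable:
    """LENC influence score of every node.

    Combines the per-node entropies with the k-shell index and adds the
    neighbors' local influences (two-order aggregation).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("lenc_scores undefined on an empty graph")
    table = edge_influence_table(g)
    cores = k_shell(g)
    local = {}
    for m in g.nodes():
        ent = table.virtual_entropy[m] + sum(
            table.edge_entropy[(m, n)] for n in g[m]
        )
        local[m] = ent * cores[m]
    total = {m: local[m] + sum(local[n] for n in g[m]) for m in g.nodes()}
    return ScoreTable(total)
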