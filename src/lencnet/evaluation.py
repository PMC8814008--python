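"""Ranking evaluation: Kendall τ and the β-sweep consistency experiment.

The default τ is the tau-a form

    τ(X, Y) = (n_c − n_d) / (0.5·n·(n − 1)),

where tied pairs count as neither concordant nor discordant but stay in
the denominator.  This differs from the more common tau-b (scipy's
default), which rescales the denominator for ties; tau-b is available
via ``variant="b"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .lenc import ScoreTable
from .sir import SIRParams, node_spreading_scores


def kendall_tau(x, y, variant: str = "a") -> float:
    """Kendall rank correlation between two equal-length score sequences.

    ``variant="a"``: (concordant − discordant) / (n(n−1)/2), ties
    excluded from the numerator only.  ``variant="b"``: scipy's
    tie-adjusted form.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least two observations")
    if variant == "b":
        return float(stats.kendalltau(x, y).statistic)
    if variant != "a":
        raise ValueError(f"unknown variant: {variant!r}")
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    prod = dx * dy
    nc = int(np.sum(prod > 0)) // 2
    nd = int(np.sum(prod < 0)) // 2
    return (nc - nd) / (0.5 * n * (n - 1))


def top_k(table: ScoreTable, k: int) -> list:
    """First ``k`` nodes by rank (deterministic under the tie-break rule)."""
    return table.top(k)


@dataclass
class TauCurve:
    """Kendall τ between method rankings and SIR spreading, per β."""

    beta_grid: list
    tau: dict  # (method name, beta) -> tau

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"method": name, "beta": beta, "tau": t}
            for (name, beta), t in self.tau.items()
        ]
        return pd.DataFrame(rows, columns=["method", "beta", "tau"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_beta_grid() -> list[float]:
    """Infection probabilities 0.01 … 0.10 in steps of 0.01."""
    return [round(0.01 * i, 2) for i in range(1, 11)]


def tau_sweep(
    g: nx.Graph,
    methods: dict[str, ScoreTable],
    beta_grid: list[float],
    params: SIRParams,
) -> TauCurve:
    """τ between each method's scores and SIR spreading sizes, per β.

    For each β one set of per-node spreading scores is simulated (with a
    β-specific substream of ``params.seed``) and compared against every
    method's raw score vector over the common node order.
    """
    nodes = list(g.nodes())
    for name, table in methods.items():
        missing = set(nodes) - set(table.score)
        if missing:
            raise ValueError(f"method {name!r} misses scores for {len(missing)} node(s)")
    tau: dict = {}
    for i, beta in enumerate(beta_grid):
        p = SIRParams(
            beta=beta,
            gamma=params.gamma,
            runs=params.runs,
            max_steps=params.max_steps,
            seed=(params.seed + 7919 * (i + 1)) % (2**31),
        )
        sir_scores = node_spreading_scores(g, p)
        y = [sir_scores.score[v] for v in nodes]
        for name, table in methods.items():
            x = [table.score[v] for v in nodes]
            tau[(name, beta)] = kendall_tau(x, y)
    return TauCurve(list(beta_grid), tau)
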