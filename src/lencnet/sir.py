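"""Discrete-time stochastic SIR spreading on networks.

The compartmental Susceptible–Infected–Recovered dynamics are realized
as a synchronous contact process: at each step every infected node makes
one independent Bernoulli(β) infection attempt against each currently
susceptible neighbor, and after the infection phase every infected node
recovers with probability γ.  Newly infected nodes cannot transmit, and
cannot recover, in the step of their infection.  A run ends when no
infected node remains (or a safety cap of steps is reached).

With γ = 1 each node is infectious for exactly one step, which is the
setting of all reference experiments here.  The per-node spreading score
is the mean final outbreak size over many runs seeded at that node; the
top-k experiment tracks the cumulative ever-infected count F(t) when the
k best-ranked nodes are seeded together.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .graph_core import mean_degree_moments
from .lenc import ScoreTable


@dataclass
class SIRParams:
    """Parameters of the stochastic SIR contact process.

    beta:      per-contact infection probability per step, in [0, 1].
    gamma:     per-step recovery probability, in (0, 1].
    runs:      number of independent repetitions for averaged quantities.
    max_steps: safety cap on steps per run; ``None`` means 10·|V|.
    seed:      master seed; all randomness derives from it.
    """

    beta: float
    gamma: float = 1.0
    runs: int = 1000
    max_steps: int | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"gamma must be in (0, 1], got {self.gamma}")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


@dataclass
class SIRRun:
    """Outcome of a single realization."""

    recovered: set
    cumulative: list  # ever-infected count after each step
    steps: int
    states: list = field(default_factory=list)  # (|S|, |I|, |R|) per step, if tracked

    @property
    def final_size(self) -> int:
        return len(self.recovered)


@dataclass
class SIROutcome:
    """Aggregate of many realizations from the same seed set."""

    final_sizes: list
    trajectory: list = field(default_factory=list)  # mean cumulative F(t)
    steps: list = field(default_factory=list)

    @property
    def mean_final_size(self) -> float:
        return float(np.mean(self.final_sizes))

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": range(1, len(self.trajectory) + 1),
                "mean_cumulative_infected": self.trajectory,
            }
        )


def epidemic_beta(g: nx.Graph) -> float:
    """Degree-moment infection probability 2⟨k⟩/⟨k²⟩, clamped to [0, 1].

    Twice the epidemic-threshold estimate β_c = ⟨k⟩/⟨k²⟩ of uncorrelated
    networks, i.e. comfortably supercritical but still sparse spreading.
    """
    k1, k2 = mean_degree_moments(g)
    if k2 == 0:
        raise ValueError("epidemic_beta undefined: graph has no edges")
    return min(1.0, 2.0 * k1 / k2)


def simulate_sir(
    g: nx.Graph, seeds, params: SIRParams, rng: random.Random,
    track_states: bool = False,
) -> SIRRun:
    """One realization of the contact process seeded at ``seeds``.

    Returns the final recovered set and the cumulative ever-infected
    count after each step; with ``track_states`` the (|S|, |I|, |R|)
    compartment counts are also recorded per step.  If the step cap
    fires with infections still active, the remaining infected nodes are
    counted as recovered so that the final size always equals the
    ever-infected count.
    """
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seed set must be non-empty")
    unknown = seeds - set(g.nodes())
    if unknown:
        raise KeyError(f"seed nodes not in graph: {sorted(map(str, unknown))}")
    max_steps = params.max_steps if params.max_steps is not None else 10 * g.number_of_nodes()
    beta, gamma = params.beta, params.gamma

    n_total = g.number_of_nodes()
    infected = set(seeds)
    recovered: set = set()
    cumulative: list[int] = []
    states: list[tuple[int, int, int]] = []
    steps = 0
    rand = rng.random
    while infected and steps < max_steps:
        newly: set = set()
        if beta > 0.0:
            for u in infected:
                for v in g[u]:
                    # one Bernoulli trial per infected-susceptible contact
                    if v in infected or v in recovered or v in newly:
                        continue
                    if rand() < beta:
                        newly.add(v)
        if gamma >= 1.0:
            recovered |= infected
            infected = newly
        else:
            still = {u for u in infected if rand() >= gamma}
            recovered |= infected - still
            infected = still | newly
        steps += 1
        cumulative.append(len(infected) + len(recovered))
        if track_states:
            states.append(
                (n_total - len(infected | recovered), len(infected), len(recovered))
            )
    if infected:  # step cap fired
        recovered |= infected
    return SIRRun(recovered, cumulative, steps, states)


def run_sir(g: nx.Graph, seeds, params: SIRParams) -> SIROutcome:
    """``params.runs`` independent realizations; mean F(t) padded at the tail.

    Shorter runs hold their final cumulative value for the remaining
    steps, so the mean trajectory is defined up to the longest run and
    is non-decreasing.
    """
    rng = random.Random(params.seed)
    finals, lengths, curves = [], [], []
    for _ in range(params.runs):
        out = simulate_sir(g, seeds, params, rng)
        finals.append(out.final_size)
        lengths.append(out.steps)
        curves.append(out.cumulative)
    horizon = max((len(c) for c in curves), default=0)
    traj = []
    for t in range(horizon):
        vals = [c[t] if t < len(c) else c[-1] for c in curves]
        traj.append(float(np.mean(vals)))
    return SIROutcome(finals, traj, lengths)


def node_spreading_scores(g: nx.Graph, params: SIRParams) -> ScoreTable:
    """Mean final outbreak size when each node alone seeds the epidemic.

    Each node gets an independent substream derived from ``params.seed``,
    so results do not depend on node iteration order.
    """
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(g.number_of_nodes())
    scores = {}
    for v, child in zip(g.nodes(), children):
        rng = random.Random(int(child.generate_state(1, dtype=np.uint64)[0] >> 1))
        sizes = [simulate_sir(g, {v}, params, rng).final_size for _ in range(params.runs)]
        scores[v] = float(np.mean(sizes))
    return ScoreTable(scores)


def topk_trajectory(g: nx.Graph, ranking: ScoreTable, k: int, params: SIRParams) -> SIROutcome:
    """Seed the top-``k`` nodes of ``ranking`` and average F(t) over runs."""
    if k > g.number_of_nodes():
        raise ValueError(f"k={k} exceeds number of nodes {g.number_of_nodes()}")
    seeds = ranking.top(k)
    return run_sir(g, seeds, params)
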