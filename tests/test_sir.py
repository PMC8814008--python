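"""SIR contact process: limit laws, conservation, and enumeration oracles."""

import itertools
import math
import random

import networkx as nx
import numpy as np
import pytest

from lencnet.sir import (
    SIRParams,
    epidemic_beta,
    node_spreading_scores,
    run_sir,
    simulate_sir,
    topk_trajectory,
)
from lencnet.lenc import ScoreTable


def _enumerate_final_size(g: nx.Graph, seeds, beta: float) -> float:
    """Exact expected final size for gamma = 1 by exhaustive enumeration.

    With certain recovery, every node is infectious for exactly one step,
    so the process is a breadth-first percolation whose outcome tree is
    finite; branch over the subset of susceptible contacts infected at
    each step.
    """

    def step(infected: frozenset, recovered: frozenset) -> float:
        if not infected:
            return float(len(recovered))
        # contacts: susceptible neighbor -> number of infected contacts
        contacts = {}
        for u in infected:
            for v in g[u]:
                if v not in infected and v not in recovered:
                    contacts[v] = contacts.get(v, 0) + 1
        targets = sorted(contacts)
        probs = [1.0 - (1.0 - beta) ** contacts[v] for v in targets]
        total = 0.0
        for outcome in itertools.product([0, 1], repeat=len(targets)):
            p = 1.0
            newly = []
            for v, hit, pv in zip(targets, outcome, probs):
                p *= pv if hit else (1.0 - pv)
                if hit:
                    newly.append(v)
            if p == 0.0:
                continue
            total += p * step(frozenset(newly), recovered | infected)
        return total

    return step(frozenset(seeds), frozenset())


class TestParams:
    def test_beta_out_of_range(self):
        with pytest.raises(ValueError):
            SIRParams(beta=1.5)

    def test_gamma_zero_rejected(self):
        with pytest.raises(ValueError):
            SIRParams(beta=0.5, gamma=0.0)


class TestEpidemicBeta:
    def test_regular_graph(self):
        # d-regular: 2d/d^2 = 2/d
        assert epidemic_beta(nx.cycle_graph(10)) == pytest.approx(1.0)
        assert epidemic_beta(nx.complete_graph(5)) == pytest.approx(0.5)

    def test_toy(self, toy):
        assert epidemic_beta(toy) == pytest.approx(0.7)

    def test_clamped_to_one(self):
        assert epidemic_beta(nx.path_graph(2)) == 1.0

    def test_edgeless_graph_rejected(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        with pytest.raises(ValueError):
            epidemic_beta(g)


class TestLimitLaws:
    def test_beta_zero_final_equals_seeds(self, karate):
        params = SIRParams(beta=0.0, gamma=1.0)
        out = simulate_sir(karate, {"1", "34"}, params, random.Random(0))
        assert out.final_size == 2

    def test_certain_transmission_fills_component(self, toy):
        params = SIRParams(beta=1.0, gamma=1.0)
        out = simulate_sir(toy, {"5"}, params, random.Random(0))
        assert out.final_size == 6

    def test_certain_transmission_respects_components(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("x", "y")])
        params = SIRParams(beta=1.0, gamma=1.0)
        out = simulate_sir(g, {"a"}, params, random.Random(0))
        assert out.recovered == {"a", "b", "c"}

    def test_empty_seed_set_rejected(self, toy):
        with pytest.raises(ValueError):
            simulate_sir(toy, set(), SIRParams(beta=0.5), random.Random(0))

    def test_unknown_seed_rejected(self, toy):
        with pytest.raises(KeyError):
            simulate_sir(toy, {"99"}, SIRParams(beta=0.5), random.Random(0))


class TestConservation:
    def test_compartments_partition_nodes_every_step(self, karate):
        n = karate.number_of_nodes()
        rng = random.Random(42)
        params = SIRParams(beta=0.2, gamma=0.5)
        for _ in range(50):
            out = simulate_sir(karate, {"1"}, params, rng, track_states=True)
            for s, i, r in out.states:
                assert s + i + r == n

    def test_cumulative_is_monotone(self, karate):
        rng = random.Random(1)
        params = SIRParams(beta=0.3, gamma=0.7)
        for _ in range(20):
            out = simulate_sir(karate, {"1"}, params, rng)
            assert all(a <= b for a, b in zip(out.cumulative, out.cumulative[1:]))
            assert out.final_size == out.cumulative[-1]


class TestEnumerationOracles:
    def test_triangle_matches_exact_expectation(self):
        g = nx.complete_graph(3)
        beta = 0.5
        exact = _enumerate_final_size(g, {0}, beta)
        runs = 20_000
        params = SIRParams(beta=beta, gamma=1.0, runs=runs, seed=2024)
        out = run_sir(g, {0}, params)
        sizes = np.asarray(out.final_sizes, dtype=float)
        se = sizes.std(ddof=1) / math.sqrt(runs)
        assert abs(sizes.mean() - exact) <= 3 * se

    @pytest.mark.parametrize(
        "edges,seeds,beta",
        [
            ([(0, 1), (1, 2), (2, 3)], {1}, 0.3),  # path
            ([(0, 1), (0, 2), (0, 3)], {0}, 0.4),  # star
            ([(0, 1), (1, 2), (2, 0), (2, 3)], {0}, 0.5),  # triangle + pendant
        ],
    )
    def test_one_step_expectation(self, edges, seeds, beta):
        """After one step the expected cumulative count has a closed form."""
        g = nx.Graph(edges)
        contacts = {}
        for u in seeds:
            for v in g[u]:
                if v not in seeds:
                    contacts[v] = contacts.get(v, 0) + 1
        exact = len(seeds) + sum(1 - (1 - beta) ** c for c in contacts.values())
        runs = 20_000
        rng = random.Random(99)
        params = SIRParams(beta=beta, gamma=1.0, max_steps=1)
        vals = [
            simulate_sir(g, seeds, params, rng).cumulative[0] for _ in range(runs)
        ]
        vals = np.asarray(vals, dtype=float)
        se = vals.std(ddof=1) / math.sqrt(runs)
        assert abs(vals.mean() - exact) <= 3 * se


class TestReproducibilityAndMonotonicity:
    def test_identical_seed_identical_outcome(self, karate):
        params = SIRParams(beta=0.2, gamma=1.0, runs=50, seed=5)
        a = run_sir(karate, {"1"}, params)
        b = run_sir(karate, {"1"}, params)
        assert a.final_sizes == b.final_sizes
        assert a.trajectory == b.trajectory

    def test_mean_final_size_monotone_in_beta(self):
        g = nx.gnp_random_graph(30, 0.15, seed=8)
        means, ses = [], []
        for beta in (0.1, 0.3, 0.6):
            params = SIRParams(beta=beta, gamma=1.0, runs=2000, seed=13)
            sizes = np.asarray(run_sir(g, {0}, params).final_sizes, dtype=float)
            means.append(sizes.mean())
            ses.append(sizes.std(ddof=1) / math.sqrt(len(sizes)))
        assert means[1] >= means[0] - 3 * (ses[0] + ses[1])
        assert means[2] >= means[1] - 3 * (ses[1] + ses[2])


class TestSpreadingScores:
    def test_beta_zero_all_ones(self, toy):
        params = SIRParams(beta=0.0, gamma=1.0, runs=5, seed=0)
        assert set(node_spreading_scores(toy, params).score.values()) == {1.0}

    def test_certain_transmission_all_n(self, toy):
        params = SIRParams(beta=1.0, gamma=1.0, runs=3, seed=0)
        assert set(node_spreading_scores(toy, params).score.values()) == {6.0}

    def test_karate_hub_beats_leaf(self, karate):
        params = SIRParams(beta=epidemic_beta(karate), gamma=1.0, runs=400, seed=17)
        table = node_spreading_scores(karate, params)
        # node 34 is the main hub (degree 17); node 12 is a leaf
        assert table.score["34"] > table.score["12"]

    def test_deterministic_given_seed(self, toy):
        params = SIRParams(beta=0.5, gamma=1.0, runs=30, seed=3)
        a = node_spreading_scores(toy, params).score
        b = node_spreading_scores(toy, params).score
        assert a == b


class TestTopKTrajectory:
    def test_all_nodes_seeded_constant(self, toy):
        ranking = ScoreTable({v: 1.0 for v in toy})
        params = SIRParams(beta=0.5, gamma=1.0, runs=10, seed=0)
        out = topk_trajectory(toy, ranking, 6, params)
        assert all(v == 6.0 for v in out.trajectory)

    def test_beta_zero_flat_at_k(self, toy):
        ranking = ScoreTable({v: float(toy.degree(v)) for v in toy})
        params = SIRParams(beta=0.0, gamma=1.0, runs=10, seed=0)
        out = topk_trajectory(toy, ranking, 3, params)
        assert all(v == 3.0 for v in out.trajectory)

    def test_certain_transmission_saturates_by_step_two(self, toy):
        from lencnet.lenc import lenc_scores

        ranking = lenc_scores(toy)  # top-2 = {4, 3}
        params = SIRParams(beta=1.0, gamma=1.0, runs=5, seed=0)
        out = topk_trajectory(toy, ranking, 2, params)
        assert out.trajectory[min(1, len(out.trajectory) - 1)] == 6.0

    def test_k_too_large_rejected(self, toy):
        ranking = ScoreTable({v: 1.0 for v in toy})
        with pytest.raises(ValueError):
            topk_trajectory(toy, ranking, 7, SIRParams(beta=0.5))
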