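# Methods

## Graph model

Networks are undirected simple graphs (`networkx.Graph`). Node ids are
opaque strings; numeric-looking ids are never coerced, and the reader
preserves them exactly as written. Self-loops are dropped and duplicate
edges collapsed at parse time (counts logged at DEBUG), because every
formula below assumes a simple graph. Insertion order of nodes is
preserved, so iteration order — and with it every seeded computation —
is reproducible.

## The LENC construction

All degrees in the edge-weight formulas are *original-graph* degrees.
The virtual node is a pure bookkeeping device: it contributes one term
`W_mv' = k_m²N/(k_m + N)` per node (the edge-weight formula with
triangle count 0 and partner degree N = number of real nodes) but is
never materialized in the graph and never alters any degree or core
index. Its purpose is discrimination: without it a degree-1 node has a
single weight fraction p = 1 and hence zero entropy, making all leaves
(and more generally nodes with identically-shaped weight distributions)
indistinguishable.

Conventions:

- The intrinsic edge weight `w_mn` is fixed to 1. The `edge_weight`
  function exposes it as an optional argument for weighted-network
  experiments, but nothing in the package exercises it.
- Logarithms are base 2 throughout; `0·log₂0` is defined as 0
  defensively, although a real edge of a simple graph always has
  `W_mn > 0` (its triangle count is at most `min(k_m, k_n) − 1`).
- Isolated nodes: total weight 0 ⇒ entropy 0 ⇒ influence 0, and their
  k-shell index is 0. This is the monotone-safe convention for inputs
  with singleton components.
- The "entropy × k-core" position scaling is a plain product, and the
  aggregation stops at second order (a node's own local influence plus
  its neighbors'); no higher-order extension is attempted.
- Rank ties are broken by ascending node id (string order), so score
  tables are deterministic across platforms.

## Baselines

Closeness, eigenvector centrality, and HITS delegate to networkx.
Closeness uses component-restricted distances with Wasserman–Faust
scaling `(n_c−1)/(|V|−1)` so disconnected inputs are handled gracefully;
singleton components score 0. Eigenvector centrality and HITS iterate
to tolerance 1e−10 with a 1000-iteration cap and raise on
non-convergence; on undirected graphs HITS authorities equal the
eigenvector ranking, which the tests assert as a cross-check.

H-index (largest h such that ≥ h neighbors have degree ≥ h) and DIL are
implemented here. **DIL is a reconstruction**: the formula

    DIL(i) = k_i + Σ_{j∈Γ(i)} (U/λ)·(k_i−1)/(k_i+k_j−2),
    U = (k_i−p−1)(k_j−p−1),  λ = p/2 + 1,  p = common neighbors of (i,j),

with the `k_i + k_j = 2` degeneracy (an isolated edge) contributing 0,
follows the originally published degree-and-importance-of-lines measure;
variants exist in the literature, and an order-1 evaluation is used.

## SIR simulator

The compartmental SIR dynamics are realized as a **discrete-time
synchronous contact process**, the standard reading for network
experiments: per step, every infected node makes one independent
Bernoulli(β) attempt against each currently susceptible neighbor; after
the infection phase each infected node recovers with probability γ.
Newly infected nodes neither transmit nor recover in the step of their
infection. A run ends at extinction, with a safety cap of 10·|V| steps
(if the cap fires, still-infected nodes are counted into the final size
so that final size always equals the ever-infected count). Multiple
infected neighbors of the same susceptible node attempt independently —
equivalently, infection occurs with probability 1 − (1−β)^c for c
infectious contacts, which is exactly what the exact-enumeration oracle
in the tests computes.

- `F(t)` is reported as the cumulative ever-infected count (I + R),
  hence monotone non-decreasing; shorter runs hold their final value
  when trajectories are averaged.
- The default infection probability is the degree-moment heuristic
  `β = 2⟨k⟩/⟨k²⟩` — twice the epidemic-threshold estimate of
  uncorrelated networks — clamped to [0, 1] (sparse near-regular graphs
  can push it above 1).
- γ defaults to 1 (each node infectious for exactly one step), matching
  the reference experimental protocol.
- All randomness flows from one integer seed. Per-node spreading scores
  give each node an independent substream (via `numpy.random.
  SeedSequence.spawn`), so results do not depend on iteration order;
  the β-sweep derives one substream per grid point.

## Kendall τ

The default correlation is **tau-a**: (n_c − n_d) / (0.5·n·(n−1)), with
tied pairs counted as neither concordant nor discordant but left in the
denominator. This is deliberately not scipy's tau-b (which rescales the
denominator under ties); tau-b is available via `variant="b"`. τ is
computed on raw scores; by monotone invariance this equals τ on rank
positions except in the presence of ties. The β grid for consistency
sweeps defaults to 0.01…0.10 in steps of 0.01.

## Synthetic data and what the tests show

The generators wrap the standard Erdős–Rényi, Barabási–Albert and
Watts–Strogatz constructions with explicit seeds and string ids. They
emulate the *topological* regimes the method cares about — homogeneous
(ER), scale-free (BA), small-world (WS) — but not degree correlations,
community structure, or the sheer scale of real interaction networks
(10³–10⁵ nodes), so passing tests demonstrate correctness of the
computation and qualitative behavior, not effect sizes on real data.

Problem sizes were chosen so the whole suite runs on a laptop core in
well under ten minutes: the consistency experiment uses a BA graph with
n = 200, m = 3 and 500 SIR runs per node (measured τ(LENC, SIR) ≈ 0.77
at β = 2⟨k⟩/⟨k²⟩ ≈ 0.17), the enumeration oracle uses 20 000 runs on a
triangle, and statistical assertions use 3-standard-error margins.

## Numerical choices

- Entropy-term tolerance in invariant tests: per-node weight fractions
  must sum to 1 within 1e−9.
- Golden-value tests assert to 4 printed decimals (abs 1.1e−4: the
  reference values are truncated, not rounded, in places).
- The small-graph oracle compares the implementation against a
  deliberately naive equation-literal reference on all 996 connected
  graphs with ≤ 7 nodes (networkx Graph Atlas) at 1e−9.

## Design choices where the design was open

- The CLI covers the three experiment protocols (`rank`, `sir`,
  `kendall`) with flags only; a config-file layer was omitted as
  redundant — every run parameter is a single flag, and commands are
  pure functions of (input, flags, seed).
- Per-node SIR runs in the β-sweep default to 500; single-protocol runs
  default to 1000.
- The karate network ships 1-based (nodes "1"–"34"), the convention of
  the social-network literature.

## Known limitations

- Directed and weighted networks are out of scope (the `w_mn` hook
  exists but is untested territory).
- The SIR simulator is for validation at network scale, not an ODE
  integrator; no SIS/SEIR variants.
- DIL is a reconstruction (above); other published variants of the
  measure would rank some nodes differently.
- Scores are float64; on graphs with massive automorphism groups,
  equality of equivalent nodes' scores holds to ~1e−12, not bit-exactly.
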