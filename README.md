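# lencnet

Identifying influential spreaders in networks with a local-structure
entropy centrality (LENC), plus the full validation toolkit: baseline
centralities, a stochastic SIR spreading simulator, and Kendall-τ
consistency analysis.

## The problem

In contact networks — protein interactions, email traffic, social ties —
a handful of nodes dominates how far an epidemic or a rumor spreads.
Global measures such as closeness or betweenness find them but scale
poorly; pure degree or k-shell measures are cheap but coarse, and cannot
separate nodes whose local wiring differs in ways that matter for
spreading. LENC scores every node from purely local structure
(two-order neighborhood) in roughly `O(N⟨k⟩² + |E|)` time.

## The score

For an edge (m, n) with degrees `k_m, k_n` and triangle count
`T_mn = |Γ(m) ∩ Γ(n)|`, the directed edge weight seen from `m` is

    W_mn = (k_m − T_mn)(k_n − T_mn) · R_mn · w_mn / (T_mn/2 + 1),
    R_mn = k_m / (k_m + k_n),   w_mn = 1,

so an edge with many alternative triangle paths carries less weight, and
the same edge weighs differently at its two ends (`W_mn ≠ W_nm`). Every
node also receives one *virtual edge* to an auxiliary node of degree
N = |V|, weighted `W_mv' = k_m²N/(k_m + N)`; without it all leaves would
have zero entropy and be indistinguishable. The fractions
`p = W/W_m` over a node's edges (virtual included) form a probability
distribution; its Shannon entropy `Entropy(m) = Σ −p log₂ p` times the
node's k-shell index gives the local influence, and the final score adds
the neighbors' local influences:

    influence(m) = Entropy(m) · k-core(m)
    Influence(m) = influence(m) + Σ_{n∈Γ(m)} influence(n).

## Worked example

The bundled 6-node toy network (edges 1–2, 2–3, 2–4, 3–4, 3–6, 4–5,
4–6) has closed-form values for every intermediate:

```python
>>> import lencnet as L
>>> g = L.toy_network()
>>> L.virtual_edge_weight(g, "4")      # k=4, N=6: 16*6/10
9.6
>>> L.edge_weight(g, "4", "2")         # (4-1)(3-1)/1.5 * 4/7
2.2857142857142856
>>> L.node_total_weight(g, "4")
16.99047619047619
>>> L.node_entropy(g, "4")
1.7610548225680458
>>> L.lenc_scores(g).to_frame()
  node      score  rank
0    4  12.890255     1
1    3  11.891113     2
2    2  10.595335     3
3    6   8.440839     4
4    5   4.521252     5
5    1   4.447065     6
```

Node 4 (the hub, degree 4) ranks first; the two leaves rank last, but —
thanks to the virtual edge — with *different* scores reflecting their
different hubs. The same ranking falls out of a node-deletion argument
on this network, which is the sanity anchor for the method.

Validation against spreading, from the command line:

```
lencnet rank    --input net.edges --method lenc,degree,dil --output-dir out/
lencnet sir     --input net.edges --beta auto --gamma 1 --runs 1000 --output-dir out/
lencnet sir     --input net.edges --beta 0.01 --gamma 1 --topk 10 --output-dir out/
lencnet kendall --input net.edges --methods lenc,degree --runs 500 --output-dir out/
```

`--beta auto` resolves to the degree-moment heuristic `2⟨k⟩/⟨k²⟩`
(twice the uncorrelated-network epidemic threshold). The `kendall`
command sweeps β over 0.01…0.10 and writes the tau-a correlation between
each method's scores and per-node SIR outbreak sizes.

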