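# hsmnet

Hierarchy inference for directed networks by **hierarchy-score
maximization (HSM)**.

Directed biological networks — transcription-factor regulomes,
kinase–substrate phosphorylomes, food webs, neural wiring — often have a
top-to-bottom command structure: some nodes act as master regulators,
others as downstream effectors. `hsmnet` infers that structure, scores
how hierarchical a network is on a scale comparable across networks, and
tests whether the hierarchy could have arisen by chance.

## The method

Given an assignment of every node to one of *L* levels (1 = bottom,
*L* = top), each edge is **downward** (higher → lower level), **upward**
(lower → higher) or **horizontal** (same level; self-loops included).
With class counts *N*<sub>d</sub>, *N*<sub>u</sub>, *N*<sub>h</sub>, the
**hierarchy score** is

HS = (*N*<sub>d</sub> + *N*<sub>h</sub>) / (*N*<sub>u</sub> + *N*<sub>h</sub>),

which is +∞ for a perfect hierarchy (no upward or horizontal edges).
HSM finds the level assignment maximizing HS by simulated annealing
(energy *E* = −HS, Metropolis acceptance exp(−Δ*E*/*CT*), geometric
cooling), repeats the optimization *k* independent times, and aggregates
the runs into a node × level **probability matrix** — nodes whose level
is ambiguous get spread-out rows instead of a false point estimate.
Three companions make the result usable in practice:

- **CHS** (corrected hierarchy score) divides each observed class count
  by its expectation under random edge placement given the level sizes
  (E(*N*<sub>d</sub>) = Σ<sub>i&gt;j</sub> *S*<sub>i</sub>*S*<sub>j</sub>, …),
  making scores comparable across level counts and across networks
  (≈ 1 for a random assignment, ∞ for a perfect tree);
- **PHS** (probabilistic hierarchy score) evaluates HS on the per-edge
  down/up/horizontal probabilities induced by the probability matrix;
- an empirical **significance test** compares the optimized HS with that
  of Erdős–Rényi digraphs with the same node and edge counts
  (empirical *p*, *z* = (HS − μ)/σ, Bonferroni over the tested *L*
  values).

Classical asymmetry metrics — one-minus dyadic reciprocity, the
Krackhardt hierarchy score and global reaching centrality — are included
for comparison (`hsmnet.metrics`), and `hsmnet.levels` provides
level-band statistics: binomial enrichment of interactions within and
between top/middle/bottom bands, hypergeometric shared-partner
cooperativity, the nine-type feed-forward-loop table, and a self-loop
(auto-phosphorylation) over-representation test.

## Worked example

```python
from hsmnet import (HierarchyScoreMaximizer, generate_perfect_hierarchy,
                    perturb_with_upward_edges)

ph = generate_perfect_hierarchy(seed=7)          # 19 nodes, 5 levels, 18 edges
net = perturb_with_upward_edges(ph, 3, seed=8)   # inject 3 upward edges

est = HierarchyScoreMaximizer(n_levels=5, n_runs=100, random_state=0)
est.fit(net)
print(float(est.hs_), float(est.chs_), float(est.phs_))
print(est.result_.counts)
```

prints

```
9.5 9.5 9.5
EdgeClassCounts(n_down=19, n_up=2, n_horizontal=0)
```

The optimizer recovers a leveling in which 19 of the 21 edges point
downward and only 2 of the 3 injected upward edges remain upward (one
can be absorbed by the optimal re-leveling), giving HS = 19/2 = 9.5.
With no horizontal edges CHS equals HS (the downward and upward
expectations are always equal), and the one-hot probability matrix makes
PHS coincide too. On the unperturbed tree the same call returns an
infinite HS and a probability matrix that places every node on its true
level with probability 1.

The estimator is scikit-learn compatible (`fit` / `fit_predict`,
`get_params` / `set_params`); `fit` accepts a `DirectedNetwork`, a
networkx `DiGraph`, or a square adjacency matrix, and exposes
`labels_` (levels), `probability_matrix_`, `hs_`, `chs_`, `phs_`.

## Command line

```bash
hsmnet simulate perfect --seed 3 --out military     # edge list + truth levels
hsmnet metrics military.tsv                          # {one_minus_dr, khs, grc}
hsmnet infer military.tsv --levels 2..8 --runs 1000 --seed 1 --out results/
hsmnet score military.tsv results/levels.tsv
hsmnet significance military.tsv --nulls 1000
hsmnet levels-analyze results/levels.tsv --interactions pairs.tsv
```

`infer` tries each level count, picks the smallest L whose CHS is within
2 % of the best (CHS saturation), and writes `levels.tsv`,
`probability_matrix.tsv` and `scores.json`.

### Analyzing published interaction datasets

Cross-network comparisons (e.g. regulome vs phosphorylome) use exactly
the same file-based workflow: download an interaction dataset from its
original publication or database, reduce it to the regulator–regulator
(TF–TF or kinase–kinase) edge list as a two-column TSV, then run
`hsmnet metrics`, `hsmnet infer` and `hsmnet significance` on it.
Absolute score values on such data depend on the optimization effort
(`--runs`, `--steps`), so report those settings alongside the scores.
No third-party dataset is bundled here.

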