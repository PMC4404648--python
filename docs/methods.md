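# Methods

## Model

A hierarchy over a directed network is an assignment of every node to a
level in 1..L (bottom to top). Edges are classified downward, upward or
horizontal by the level difference of their endpoints; self-loops are
horizontal by construction. The hierarchy score
HS = (N_d + N_h)/(N_u + N_h) rises as downward flow dominates, is 1 when
downward and upward flow balance, and is +inf when N_u = N_h = 0.
Inference means maximizing HS over the L^n possible assignments, a
combinatorial problem we attack with simulated annealing. The model
assumes an unweighted, binary edge set: duplicate interactions are
collapsed on input, and no weighting of edges enters any score.

Scores are carried as exact numerator/denominator pairs
(`ScoreValue`); comparisons cross-multiply, so +inf states and
exact-equality checks (e.g. against enumeration) involve no float
rounding.

## Annealing

One schedule starts from a uniformly random assignment (energy
E = -HS), proposes moving a uniformly random node to a uniformly random
different level, accepts improvements outright and deteriorations with
probability exp(-dE/(C T)), and cools geometrically from T0 to a final
temperature:

- steps per schedule p: default 400 * n * L. On every network studied
  here the HS-vs-p curve saturates well below this; the default buys
  convergence headroom at small cost since a step touches only the
  moved node's neighbors.
- T0 = 1, final T = 1e-3 (cooling rate (1e-3)^(1/p)), C = 1. dE is on
  the HS scale, which is O(1) early in a run; the final temperature
  freezes the state once the score is locked in.
- restarts: each aggregated run is the best of `n_restarts = 3`
  independent schedules. Near-perfect assignments sit on ratio cliffs
  of HS (leaving an HS ~ 18 state toward the global +inf optimum passes
  through HS ~ 8 valleys), so a schedule that lands in a shifted-subtree
  local optimum cannot be rescued by any usable temperature; independent
  restarts cube the per-schedule miss probability instead. At the
  defaults, 1,500 consecutive runs on the 19-node planted hierarchy all
  reached the global optimum.
- best-seen tracking: a run returns the best assignment ever visited,
  not the final state, so late uphill acceptances are harmless. An
  infinite-HS state is never exited (the acceptance probability of
  leaving it is exp(-inf) = 0).

k runs (default 1,000; frequencies are stable beyond ~100) are
aggregated into the probability matrix: entry (i, l) is the fraction of
runs assigning node i to level l, so rows sum to 1 exactly and every
entry is a multiple of 1/k. Discretization takes the per-node argmax,
ties going to the lowest level (deterministic and conservative toward
the bottom); tied nodes are reported. Per-run seeds derive from the base
seed (seed + run index; restart r of a run offsets by r), so identical
seeds give bit-identical results. Level indices are aggregated as-is
across runs with no alignment step; when distinct optima coexist (e.g.
an empty level can float), ambiguity shows up as spread probability rows
rather than being hidden.

## Level count selection

CHS corrects each observed class count by the number of ordered node
pairs in that class given the level sizes, making scores comparable
across L. `select_levels` runs the pipeline over an L range (default
2..8) and returns the smallest L whose CHS is within 2 % (configurable)
of the range maximum — the saturation rule; when some L reaches an
infinite CHS, only infinite values count as saturated. A warning is
emitted for L values exceeding the network diameter.

## Significance

`assess_significance` compares the optimized HS against G(n, m)
Erdős–Rényi digraphs with the same node and edge counts (uniform
sampling of m distinct ordered pairs, self-loops excluded by default and
available as a flag). Per L it reports the empirical p (fraction of
null optima >= observed, exact score comparison), the Gaussian z-score
and tail p from the null mean and SD, the observed/null-mean ratio and
the one-sample t statistic; the overall value is the minimum empirical p
Bonferroni-multiplied by the number of L values tested. When the
observed HS is infinite and no null reaches infinity the empirical p is
exactly 0. Degree-preserving (edge-swap) nulls are not implemented; the
generator argument is the natural extension point.

## Synthetic generators

`generate_perfect_hierarchy` emulates a command structure: level sizes
bottom-to-top (default (7, 5, 4, 2, 1) — 19 nodes over 5 levels), each
non-top node receiving exactly one parent from the level above (`tree`)
or additionally extra adjacent-level downward edges (`layered_random`).
Every non-bottom node is guaranteed at least one child in the level
directly below (level sizes must be non-increasing upward); this makes
the planted leveling the unique all-downward assignment, so a converged
HSM run recovers it with probability-1 rows. `perturb_with_upward_edges`
injects new upward edges uniformly among absent lower->higher pairs
(original edges untouched; a reverse-edge mode exists). These fixtures
deliberately lack features of real interactomes — hubs, reciprocal
edges, noise in edge direction, missing data — so recovery results on
them demonstrate optimizer correctness, not robustness to measurement
error.

## Band statistics

For T/M/B analyses an L-level assignment collapses to bands (3 levels
map directly; otherwise top level -> T, bottom -> B, middle levels -> M,
overridable). Interaction enrichment per band pair uses
Binomial(b, p) with p = e/[n(n-1)/2] and b = m(m+1)/2 slots within a
band (self-pairs included, so self-interactions are admissible) or
m1*m2 between bands; enrichment is P(X >= i), depletion P(X <= i) (the
two tails share the point mass, so they sum to >= 1). Cooperativity
calls a pair of nodes cooperative when their partner-set overlap clears
a hypergeometric (Fisher exact) test at 0.05 (configurable), then feeds
cooperative pairs to the same binomial scheme. Feed-forward loops are
triples (X -> Y, Z in substrates(X) ∩ substrates(Y), Z ∉ {X, Y}); each
shared substrate counts as one motif, accumulated over the nine ordered
band pairs of (X, Y). Self-loop over-representation uses a
Binomial(e, 1/n) upper tail — the null drops each of e edges on a
uniformly random ordered pair with self-pairs allowed; this null is one
reasonable choice among several, and is stated rather than assumed.

## Numerical and scale choices

- The desk-scale experiments use: planted recovery at k = 100 runs
  (L = 5, default steps); oracle-equivalence checks on <= 8-node graphs
  against full 3^n enumeration with exact score equality; perturbation
  trends over 20 replicates with 3 runs x 2 restarts x 20,000 steps;
  null calibration on G(1000, 2000) at L = 3 with k = 50 and
  50 * n * L steps (the HS-vs-steps curve is flat well before that at
  average degree 4), and 200 nulls against a dense 31-node planted
  hierarchy (average degree ~ 5, so every null contains cycles and a
  finite HS).
- Optimizing a null network inflates its CHS well above 1 (~2.5 on
  G(1000, 2000)): maximization converts random fluctuations into
  downward structure. The "CHS ~ 1 for a random network" intuition
  applies to a random assignment, which the tests check separately; the
  meaningful null comparison is always against other optimized nulls,
  as the significance machinery does.
- Degenerate inputs: edgeless networks have no defined score (error);
  empty levels are legal and contribute zero expected counts; E = 0
  with a positive observed count is impossible for a valid assignment
  and raises; reciprocity/Krackhardt are undefined (error) when no node
  pair is reachable.

## Known limitations

- Annealing is stochastic; exact-optimum guarantees are only verified
  for small networks by enumeration. On large dense networks the
  reported HS is a lower bound on the true maximum, improving with
  steps/runs — report effort settings with scores.
- Scores on published datasets depend on that effort and on dataset
  curation choices (which interactions are regulator-regulator), so
  cross-paper numeric comparisons need the same preprocessing.
- The binomial enrichment model treats interactions as independent
  trials, ignoring degree heterogeneity; a degree-preserving null would
  be stricter.
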