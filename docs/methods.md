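# Methods

## The attribution problem

A local similarity index scores a node pair from its common-neighbor
environment. On a weighted network the score can draw on two separable
sources of signal: which edges exist (topology) and how weight is placed
on them. `linknull` attributes prediction accuracy to these sources by
re-running the same evaluation on randomized surrogates of the network
that conserve chosen properties exactly and scramble the rest. Because
each surrogate conserves different invariants, the drop in accuracy
relative to the original isolates the contribution of what was scrambled.

## Indices

CN, AA and RA are the standard unweighted common-neighbor indices. Their
weighted forms WCN, WAA and WRA replace each common-neighbor contribution
with `w(x,z)^α + w(z,y)^α`, normalized by nothing, by `log(1 + s(z))`, or
by `s(z)` respectively. Conventions:

- **Logarithm base.** Natural log throughout. Changing base multiplies
  all AA scores by one constant and all WAA scores by another, which
  leaves every ranking — hence AUC and Precision — unchanged.
- **α = 0.** `WCN(α=0) = 2·CN` holds identically and is asserted in
  tests. WAA(α=0) and WRA(α=0) are *not* rank-equivalent to AA and RA (the
  normalizers differ: `log(1+s)` and `s` versus `log k` and `k`); the
  formulas are followed literally and no forced reduction is applied.
- **Degenerate terms.** A common neighbor z is adjacent to both endpoints
  by definition, so k(z) ≥ 2 and `log k(z) > 0` even on a training graph
  with edges removed; this is asserted, not special-cased. Weights are
  validated strictly positive at load time, so negative-α powers and the
  strength normalizers are always defined.

## Evaluation protocol

- Probe set: a uniformly random `round(0.1·|pool|)` edges (minimum 1),
  where the pool is the full edge set or, in tie experiments, one weight
  class. Training graph = all remaining edges, over the full node set.
  Scoring sees only the training graph.
- Non-edges: sampled uniformly without replacement, as many as probes; an
  error is raised when the graph is too dense to supply them.
- AUC uses exhaustive comparison of all probe/non-edge score pairs with
  half credit for ties (the sampled estimator is available for large
  candidate sets and converges to the exhaustive value).
- Precision uses L = |probe| by default, so a perfect ranking scores 1.
  Ties are ordered by a seeded random permutation; AUC needs no
  tie-break because the half-credit rule is exact.
- Null models are built from the **full** graph, once per variant; each
  repeat then splits the surrogate independently. (The original network
  and its surrogates are treated as separate networks to be predicted;
  building the surrogate from a training graph instead is possible by
  composing the builders manually.)
- The default α grid is −2…2 in steps of 0.25. Summaries report the
  maximum over α of the repeat-mean (`max_of_means`, default) or of all
  rows (`max_of_all`); the default answers "what is the best this
  variant can do on average", which is the robust reading when repeats
  are noisy.

## Null models

All five constructions operate on a copy (inputs are never mutated),
count *successful* swaps against the requested `n_swaps` (default
`2·|E|`, enough to decorrelate the edge set), and bound rejection
sampling by `100·n_swaps` attempts, after which a partial result is
returned with a warning in the report. Identical seed and input give a
bit-identical output graph.

- **1k (degree-preserving).** Double edge swap: edges (A,B), (C,D) with
  four distinct endpoints become (A,D), (B,C) when both replacements are
  absent. Each removed edge's weight travels with its first endpoint —
  (A,D) inherits w(A,B), (B,C) inherits w(C,D) — conserving the weight
  multiset. Drawn edges are randomly oriented, so both rewirings of a
  quadruple are reachable.
- **Structure-shuffling.** The same move restricted to edge pairs of
  exactly equal weight (`exact` mode); with the carrying rule above all
  four endpoint strengths are then conserved exactly. Networks with
  near-unique weights cannot be shuffled this way, so `nearest` mode
  pairs each drawn edge with the valid partner closest in weight and
  accepts when the relative difference is within `tolerance` (default
  0.05, keeping per-swap strength drift ≤ 5% of the heavier weight). Each
  accepted unequal swap perturbs exactly two nodes by |w₁ − w₂|; the
  accumulated per-node drift is reported.
- **Weight-shuffling.** Two edges with different weights trade weights;
  the edge set is untouched. Long runs converge to a uniform random
  permutation of weights over edges (verified by a chi-square test on the
  location of the maximum weight).
- **Rich-club rewiring.** Rich set = top `ceil(rich_fraction·|V|)` nodes
  by strength (default 5%, matching the usual "a few hubs" reading),
  frozen at the start of the run — moves shift strengths, and re-ranking
  mid-run would chase a moving target. The enhance move connects an
  unconnected rich pair (A,B) by sacrificing edges to non-rich neighbors
  C of A and D of B (C ≠ D, (C,D) absent), adding exactly one rich–rich
  edge per success; destroy is the inverse. Club density is therefore
  monotone along the run on the designated set. Default run length is to
  saturation, bounded by `max_iters`.
- **Strength-mixing rewiring.** Two disjoint edges are drawn; their four
  endpoints are ranked by current strength (ties broken by label). The
  assortative pairing connects ranks (1,2) and (3,4); the disassortative
  pairing, (1,4) and (2,3); the move applies only when both target edges
  are absent. The new edge containing the top-ranked endpoint inherits
  the weight of the removed edge that endpoint belonged to, and the
  partner edge takes the remaining weight — a deterministic rule that
  conserves the multiset even when one removed edge contributed both odd
  ranks. Because carried weights shift strengths, single steps are not
  individually guaranteed to move the correlation; the drift over the run
  is monitored (before/after values in the report) and is reliably in the
  commanded direction on clustered scale-free fixtures.

The measurement operators are `rich_club_coefficient` (edges inside the
rich set over possible rich pairs) and `strength_assortativity` (Pearson
correlation of endpoint strengths over symmetrized edge orientations;
undefined — an error — at zero variance).

## Tie experiments

Edges sorted by descending weight split 50/50 (odd counts give the strong
half the extra edge). A weight class straddling the boundary is split
uniformly at random under the seed, so repeated experiments sample the
boundary fairly rather than inheriting sort order. Two experiment shapes:

- *Hiding*: probes are drawn from one class only, at 10% of that class;
  the training graph keeps everything else, including the whole other
  class. This asks which edges are easier to predict.
- *Scrambling*: `rewire_1k_subset` randomizes only one class (replacement
  edges inherit subset membership, keeping the scramble closed under
  rewiring; the complement is bit-identical in the output), and standard
  prediction follows. The class whose scrambling costs more accuracy
  carried more signal.

## Synthetic networks

`fixtures.generate` plants the three ingredients the framework measures:

- **Topology**: preferential attachment from an initial clique of size
  `attachment` (edge count exactly `C(m,2) + m·(n−m)`), with a triadic
  closure step — after a new node's first edge, each further edge attaches
  to a neighbor of the previous target with probability `closure`
  (default 0.6). Closure is essential: pure preferential attachment has
  vanishing clustering, and its degree-preserving randomization is
  statistically the same ensemble, so common-neighbor prediction would
  lose nothing under 1k scrambling and the framework would have nothing
  to attribute. Default `attachment=5` gives mean degree ~10, the regime
  of the denser empirical networks this emulates (air transport, neural
  wiring).
- **Weights**: Pareto with shape `weight_tail_exponent` (default 2.0,
  visibly long-tailed), rounded up to integers by default to emulate
  count data; a continuous mode exists for experiments that need distinct
  weights.
- **Coupling**: each edge joins a pool with probability |coupling|; pooled
  weights are reassigned by rank-matching to the edge's endpoint degree
  product (descending for negative coupling). This plants a weight–
  topology correlation of tunable strength. Note that with ties (integer
  weights, repeated degree products) tie-averaged Spearman correlation
  stays below 1 even at coupling = 1.

What the generator does **not** emulate: community structure,
degree–degree correlations beyond what growth induces, multi-scale weight
heterogeneity, and the specific size/density of any particular empirical
network. Passing tests therefore demonstrate the framework's internal
consistency — conservation laws, oracle agreement, the direction of the
null hierarchy under planted coupling — not quantitative agreement with
any real system.

## Numerical and design choices

- Node labels are opaque strings across all formats; equal-weight checks
  use exact float equality (tolerance handling is explicit in `nearest`
  mode only).
- Edge keys are canonical sorted pairs; iteration orders are
  deterministic, so every seeded operation is bit-reproducible.
- Sub-seeds derive from the master seed and a label/repeat/purpose tuple
  via `SeedSequence`, so adding a variant or repeat never perturbs the
  randomness of existing cells.
- Probe-count rounding is half-up with a floor of 1.
- The acceptance script runs at n = 150 nodes (735 edges), 10 repeats,
  a 7-point α grid — sizes at which the stochastic orderings it reports
  are stable across seeds while the whole run stays lightweight.

## Known limitations

- `shuffle_structure(nearest)` scans all edges per attempt (O(|E|) per
  swap); fine up to a few thousand edges, slow beyond.
- Exhaustive AUC is quadratic in the probe count; switch to the sampled
  estimator for large splits.
- The rich-club destroy move requires a connected non-rich pair; on
  graphs whose non-rich edges are scarce it saturates early (reported via
  warnings).
- Strength assortativity is undefined on strength-regular graphs and
  raises rather than returning 0.
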