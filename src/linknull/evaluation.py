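"""Link-prediction evaluation: edge splitting, AUC, Precision, and sweeps.

The protocol hides a fraction of the edges (the probe set E^T, 10% by
default), trains on the remainder (E^P), and samples as many non-edges
(E^N) as probes.  Candidate pairs E^T ∪ E^N are scored on the *training*
graph only — probe edges are invisible to neighborhoods, degrees,
strengths and weights during scoring.

Two accuracy measures are reported:

* **AUC** — the probability that a random probe edge outscores a random
  non-edge, with half credit for ties: ``(n' + 0.5·n'') / n`` over ``n``
  probe/non-edge comparisons;
* **Precision** — the fraction of the top-L ranked candidates that are
  probe edges (L = |E^T| by default, so a perfect ranking scores 1).
  Ties are broken by a seeded random permutation.

:func:`run_sweep` orchestrates factorial experiments over network
variants (the original and any null models), similarity indices, a grid
of weight exponents α, and repeated splits; :func:`max_over_alpha`
reduces the sweep to the per-variant maxima.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .graph_core import Edge, WeightedGraph, canonical_edge
from .similarity import IndexSpec, ScoreTable, score_candidates

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "LinkSplit",
    "EvalResult",
    "SweepTable",
    "split_edges",
    "training_graph",
    "auc",
    "precision_at",
    "evaluate_split",
    "run_sweep",
    "max_over_alpha",
    "derive_seed",
]

#: Default α grid: −2 … 2 in steps of 0.25 (includes the −0.5 point where
#: weak-tie amplification typically peaks).
DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(x / 4.0 for x in range(-8, 9))


def derive_seed(master: int, *components: int | str) -> int:
    """Stable sub-seed derivation: mixes the master seed with labels.

    Each (label, repeat, purpose) combination maps to an independent
    31-bit seed, so adding a variant or repeat never perturbs the
    randomness of the others.
    """
    entropy = [int(master) & 0x7FFFFFFF]
    for c in components:
        if isinstance(c, str):
            entropy.append(zlib.crc32(c.encode("utf-8")))
        else:
            entropy.append(int(c) & 0xFFFFFFFF)
    return int(np.random.SeedSequence(entropy).generate_state(1)[0]) % (2**31)


@dataclass(frozen=True)
class LinkSplit:
    """A train/probe/non-edge partition for one evaluation round.

    ``training ∪ probe`` is the full edge set, the two are disjoint, and
    ``|nonedges| == |probe|`` with every non-edge absent from the graph.
    """

    training: frozenset[Edge]
    probe: frozenset[Edge]
    nonedges: frozenset[Edge]
    seed: int


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_edges(
    graph: WeightedGraph,
    test_fraction: float = 0.1,
    restrict_to: Iterable[Edge] | None = None,
    rng_seed: int = 0,
) -> LinkSplit:
    """Sample a probe set and matching non-edges.

    The probe set is a uniformly random ``round(test_fraction·|pool|)``
    edges (minimum 1) from ``pool`` — the whole edge set, or
    ``restrict_to`` when experiments hide edges of one tie class only.
    The training set is everything else, *including* the unhidden part of
    the pool's complement.  Non-edges are sampled uniformly without
    replacement among absent pairs.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    edges = graph.edge_list()
    if restrict_to is not None:
        pool = sorted({canonical_edge(*e) for e in restrict_to})
        stray = [e for e in pool if not graph.has_edge(*e)]
        if stray:
            raise ValueError(f"restrict_to contains non-edges, e.g. {stray[0]}")
    else:
        pool = edges
    if not pool:
        raise ValueError("empty edge pool")
    rng = np.random.default_rng(rng_seed)
    n_test = max(1, _round_half_up(test_fraction * len(pool)))

    n = graph.n_nodes
    n_possible_nonedges = n * (n - 1) // 2 - graph.n_edges
    if n_possible_nonedges < n_test:
        raise ValueError(
            f"cannot sample {n_test} non-edges: only {n_possible_nonedges} exist"
        )

    idx = rng.choice(len(pool), size=n_test, replace=False)
    probe = frozenset(pool[i] for i in sorted(idx))
    training = frozenset(e for e in edges if e not in probe)

    nodes = sorted(graph.nodes)
    nonedges: set[Edge] = set()
    while len(nonedges) < n_test:
        i, j = rng.integers(n), rng.integers(n)
        if i == j:
            continue
        pair = canonical_edge(nodes[i], nodes[j])
        if graph.has_edge(*pair) or pair in nonedges:
            continue
        nonedges.add(pair)
    return LinkSplit(
        training=training, probe=probe, nonedges=frozenset(nonedges), seed=rng_seed
    )


def training_graph(graph: WeightedGraph, split: LinkSplit) -> WeightedGraph:
    """The graph visible to the predictor: training edges, all nodes."""
    tg = WeightedGraph(nodes=graph.nodes)
    for x, y in split.training:
        tg.add_edge(x, y, graph.weight(x, y))
    return tg


# ---------------------------------------------------------------------------
# metrics


def auc(
    probe_scores: Sequence[float],
    nonedge_scores: Sequence[float],
    mode: str = "exhaustive",
    n_comparisons: int | None = None,
    rng_seed: int = 0,
) -> float:
    """Probability a probe edge outscores a non-edge, ties worth half.

    ``exhaustive`` mode compares every probe score with every non-edge
    score (n = n1·n2 comparisons); ``sampled`` mode draws
    ``n_comparisons`` random probe/non-edge pairs, the classical
    estimator for large candidate sets.
    """
    p = np.asarray(probe_scores, dtype=float)
    q = np.asarray(nonedge_scores, dtype=float)
    if p.size == 0 or q.size == 0:
        raise ValueError("score sequences must be non-empty")
    if mode == "exhaustive":
        diff = p[:, None] - q[None, :]
        n_higher = int(np.count_nonzero(diff > 0))
        n_equal = int(np.count_nonzero(diff == 0))
        return (n_higher + 0.5 * n_equal) / diff.size
    if mode == "sampled":
        if not n_comparisons or n_comparisons < 1:
            raise ValueError("sampled mode needs n_comparisons >= 1")
        rng = np.random.default_rng(rng_seed)
        ps = p[rng.integers(p.size, size=n_comparisons)]
        qs = q[rng.integers(q.size, size=n_comparisons)]
        return float(np.mean((ps > qs) + 0.5 * (ps == qs)))
    raise ValueError(f"unknown mode {mode!r}")


def precision_at(
    scores: ScoreTable | Mapping[Edge, float],
    probe: Iterable[Edge],
    L: int,
    rng_seed: int = 0,
) -> float:
    """Fraction of the top-L scored candidates that are probe edges.

    Candidates are sorted by score descending; candidates with equal
    scores are ordered by a seeded random permutation so that ties at the
    L-th place are sampled fairly.
    """
    table = scores.scores if isinstance(scores, ScoreTable) else dict(scores)
    if not 1 <= L <= len(table):
        raise ValueError(f"L={L} outside 1..{len(table)}")
    probe_set = {canonical_edge(*e) for e in probe}
    rng = np.random.default_rng(rng_seed)
    pairs = sorted(table)
    tiebreak = rng.permutation(len(pairs))
    ranked = sorted(
        range(len(pairs)), key=lambda i: (-table[pairs[i]], tiebreak[i])
    )
    top = [pairs[i] for i in ranked[:L]]
    m = sum(1 for e in top if e in probe_set)
    return m / L


def evaluate_split(
    graph: WeightedGraph,
    split: LinkSplit,
    index: IndexSpec,
    L: int | None = None,
    tie_seed: int = 0,
) -> tuple[float, float]:
    """AUC and Precision of one index on one split (exhaustive AUC).

    Scores are computed on the training graph.  ``L`` defaults to the
    probe count.
    """
    tg = training_graph(graph, split)
    candidates = list(split.probe) + list(split.nonedges)
    table = score_candidates(tg, candidates, index)
    p_scores = [table.scores[e] for e in split.probe]
    q_scores = [table.scores[e] for e in split.nonedges]
    a = auc(p_scores, q_scores, mode="exhaustive")
    L = len(split.probe) if L is None else L
    prec = precision_at(table, split.probe, L, rng_seed=tie_seed)
    return a, prec


# ---------------------------------------------------------------------------
# sweeps


@dataclass(frozen=True)
class EvalResult:
    """One (variant, index, α, repeat) cell of a sweep."""

    variant: str
    index: str
    alpha: float
    repeat_id: int
    auc: float
    precision: float


@dataclass
class SweepTable:
    """Factorial sweep results over (variant × index × α × repeat)."""

    rows: list[EvalResult]
    alpha_grid: tuple[float, ...]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variant": r.variant,
                    "index": r.index,
                    "alpha": r.alpha,
                    "repeat": r.repeat_id,
                    "auc": r.auc,
                    "precision": r.precision,
                }
                for r in self.rows
            ]
        )


#: A variant builder maps (graph, seed) -> surrogate graph; ``None`` keeps
#: the original graph.
VariantBuilder = Callable[[WeightedGraph, int], WeightedGraph] | None


def run_sweep(
    graph: WeightedGraph,
    index_names: Sequence[str] = ("WCN",),
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    repeats: int = 10,
    variants: Mapping[str, VariantBuilder] | None = None,
    test_fraction: float = 0.1,
    probe_pool: Callable[[WeightedGraph, int], Iterable[Edge]] | None = None,
    L_policy: int | None = None,
    rng_seed: int = 0,
) -> SweepTable:
    """Evaluate indices across α, repeats, and network variants.

    For each variant, the surrogate network is built once from the *full*
    input graph (the original network and its null models are predicted as
    separate networks); each repeat then draws an independent
    train/probe/non-edge split of that surrogate, and every (index, α)
    combination is scored on the training graph.  Unweighted indices
    (CN/AA/RA) ignore α and contribute a single row per repeat, recorded
    at α = 0.

    ``probe_pool`` optionally restricts which edges may be hidden (e.g.
    the strong-tie half); it receives the variant graph and a seed and
    returns the pool.  All sub-seeds are derived from ``rng_seed`` and the
    variant label, so adding a variant leaves the others' randomness
    untouched.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    alpha_grid = tuple(dict.fromkeys(float(a) for a in alpha_grid))
    if not alpha_grid:
        raise ValueError("alpha_grid must be non-empty")
    if variants is None:
        variants = {"original": None}

    rows: list[EvalResult] = []
    for label, builder in variants.items():
        if builder is None:
            vgraph = graph
        else:
            vgraph = builder(graph, derive_seed(rng_seed, label, "null"))
        for r in range(repeats):
            pool = None
            if probe_pool is not None:
                pool = probe_pool(vgraph, derive_seed(rng_seed, label, r, "pool"))
            split = split_edges(
                vgraph,
                test_fraction=test_fraction,
                restrict_to=pool,
                rng_seed=derive_seed(rng_seed, label, r, "split"),
            )
            tg = training_graph(vgraph, split)
            candidates = list(split.probe) + list(split.nonedges)
            L = len(split.probe) if L_policy is None else L_policy
            tie_seed = derive_seed(rng_seed, label, r, "ties")
            for name in index_names:
                alphas = alpha_grid if IndexSpec(name).weighted else (0.0,)
                for alpha in alphas:
                    index = IndexSpec(name, alpha)
                    table = score_candidates(tg, candidates, index)
                    p_scores = [table.scores[e] for e in split.probe]
                    q_scores = [table.scores[e] for e in split.nonedges]
                    a = auc(p_scores, q_scores, mode="exhaustive")
                    prec = precision_at(table, split.probe, L, rng_seed=tie_seed)
                    rows.append(
                        EvalResult(
                            variant=label,
                            index=name,
                            alpha=alpha,
                            repeat_id=r,
                            auc=a,
                            precision=prec,
                        )
                    )
    return SweepTable(rows=rows, alpha_grid=alpha_grid)


def max_over_alpha(
    table: SweepTable | pd.DataFrame, reducer: str = "max_of_means"
) -> pd.DataFrame:
    """Reduce a sweep to per-(variant, index) maxima over the α grid.

    ``max_of_means`` (default) first averages over repeats at each α and
    then takes the best α — the summary used when reporting the maximum
    attainable accuracy of each network variant.  ``max_of_all`` takes the
    maximum over all individual rows instead.
    """
    df = table.to_dataframe() if isinstance(table, SweepTable) else table
    if df.empty:
        raise ValueError("empty sweep table")
    if reducer == "max_of_means":
        per_alpha = (
            df.groupby(["variant", "index", "alpha"])[["auc", "precision"]]
            .mean()
            .reset_index()
        )
    elif reducer == "max_of_all":
        per_alpha = df
    else:
        raise ValueError(f"unknown reducer {reducer!r}")
    out = []
    for (variant, index), grp in per_alpha.groupby(["variant", "index"]):
        i_auc = grp["auc"].idxmax()
        i_prec = grp["precision"].idxmax()
        out.append(
            {
                "variant": variant,
                "index": index,
                "auc_max": grp.loc[i_auc, "auc"],
                "auc_argmax_alpha": grp.loc[i_auc, "alpha"],
                "precision_max": grp.loc[i_prec, "precision"],
                "precision_argmax_alpha": grp.loc[i_prec, "alpha"],
            }
        )
    return pd.DataFrame(out).set_index(["variant", "index"]).sort_index()
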