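"""Seeded synthetic weighted networks for tests and experiments.

Real networks of the kind this framework targets (air-transport routes,
neural wiring, co-authorship) combine a scale-free-ish topology with a
long-tailed weight distribution, and often a correlation between the two:
heavily used links sit between well-connected nodes.  :func:`generate`
emulates exactly those three ingredients with three independent knobs —
preferential-attachment growth, Pareto-distributed weights, and a planted
rank correlation between edge weight and endpoint degree product.

:func:`toy_g0` is the small worked-example graph used throughout the
documentation, and :func:`fig_micro_cases` provides the exact before/after
configurations of each null model's elementary move, engineered so that a
single swap has only the intended move available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_core import WeightedGraph, canonical_edge

__all__ = ["FixtureSpec", "MicroCase", "generate", "toy_g0", "fig_micro_cases"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic weighted network.

    ``attachment`` is the number of edges each arriving node creates
    (growth starts from a complete graph on ``attachment`` nodes, so the
    edge count is exactly ``C(attachment, 2) + attachment·(n_nodes −
    attachment)``).  ``weight_tail_exponent`` is the Pareto shape of the
    weight distribution (heavier tail for smaller values; ≤ 3 gives
    visibly skewed weights).  ``coupling`` in [−1, 1] plants a
    topology–weight correlation: each edge independently joins the
    rank-matched pool with probability |coupling|, and pooled weights are
    reassigned so that weight rank follows degree-product rank (ascending
    for coupling > 0, reversed for coupling < 0).  ``closure`` is the
    probability that each edge after a new node's first attaches to a
    neighbor of the previous target instead of by preferential
    attachment, planting the triadic closure (clustering) that empirical
    networks show and that degree-preserving rewiring destroys; 0
    recovers pure preferential attachment.  ``discrete`` rounds weights
    up to integers, emulating count data such as flight frequencies.
    """

    n_nodes: int = 200
    attachment: int = 5
    weight_tail_exponent: float = 2.0
    coupling: float = 0.0
    closure: float = 0.6
    seed: int = 0
    discrete: bool = True

    def __post_init__(self):
        if not self.n_nodes > self.attachment >= 1:
            raise ValueError("need n_nodes > attachment >= 1")
        if self.weight_tail_exponent <= 1:
            raise ValueError("weight_tail_exponent must be > 1")
        if not -1 <= self.coupling <= 1:
            raise ValueError("coupling must lie in [-1, 1]")
        if not 0 <= self.closure <= 1:
            raise ValueError("closure must lie in [0, 1]")


def generate(spec: FixtureSpec) -> WeightedGraph:
    """Generate a synthetic weighted network from a :class:`FixtureSpec`."""
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_nodes, spec.attachment
    width = max(4, len(str(n - 1)))
    label = [f"v{i:0{width}d}" for i in range(n)]

    # preferential attachment with triadic closure, from an initial m-clique
    edges: list[tuple[int, int]] = [(i, j) for i in range(m) for j in range(i + 1, m)]
    adj: dict[int, set[int]] = {i: set(range(m)) - {i} for i in range(m)}
    # attachment probability proportional to degree: node i appears deg(i) times
    repeated: list[int] = [i for i in range(m) for _ in range(m - 1)]
    if m == 1:
        repeated = [0]  # seed node must be reachable by the first arrival
    for new in range(m, n):
        chosen: set[int] = set()
        prev: int | None = None
        while len(chosen) < m:
            t = None
            if prev is not None and rng.random() < spec.closure:
                # close a triangle through a neighbor of the previous target
                cands = sorted(adj[prev] - chosen - {new})
                if cands:
                    t = cands[int(rng.integers(len(cands)))]
            if t is None:
                t = repeated[int(rng.integers(len(repeated)))]
                if t in chosen:
                    continue
            chosen.add(t)
            prev = t
        adj[new] = set()
        for t in sorted(chosen):
            edges.append((t, new))
            adj[new].add(t)
            adj[t].add(new)
            repeated.extend((t, new))

    # Pareto (x_m = 1) weights, optionally discretized to integer counts
    weights = rng.pareto(spec.weight_tail_exponent, size=len(edges)) + 1.0
    if spec.discrete:
        weights = np.ceil(weights)

    # plant the topology-weight correlation by partial rank matching
    if spec.coupling != 0.0:
        deg = np.zeros(n, dtype=int)
        for i, j in edges:
            deg[i] += 1
            deg[j] += 1
        product = np.array([deg[i] * deg[j] for i, j in edges], dtype=float)
        pool = np.flatnonzero(rng.random(len(edges)) < abs(spec.coupling))
        if pool.size > 1:
            order = pool[np.argsort(product[pool], kind="stable")]
            sorted_w = np.sort(weights[pool])
            if spec.coupling < 0:
                sorted_w = sorted_w[::-1]
            weights[order] = sorted_w

    graph = WeightedGraph()
    for (i, j), w in zip(edges, weights):
        graph.add_edge(label[i], label[j], float(w))
    return graph


def toy_g0() -> WeightedGraph:
    """The 4-node worked example: A-C:1, B-C:2, A-D:3, B-D:1.

    Strengths are s(A)=4, s(B)=3, s(C)=3, s(D)=4; the pair (A, B) has
    common neighbors {C, D}, giving CN=2, WCN(α=1)=7, WRA(α=1)=2.
    """
    return WeightedGraph(
        [("A", "C", 1), ("B", "C", 2), ("A", "D", 3), ("B", "D", 1)]
    )


@dataclass(frozen=True)
class MicroCase:
    """One elementary null-model move: before and after configurations.

    ``after`` is the drawn outcome; ``alternates`` are the other outcomes
    consistent with the move's semantics (a double edge swap may realize
    either rewiring of the four endpoints).  ``params`` carries operation
    arguments needed to reproduce the move (e.g. the rich fraction).
    """

    name: str
    before: WeightedGraph
    after: WeightedGraph
    alternates: tuple[WeightedGraph, ...] = ()
    params: dict = field(default_factory=dict)

    def outcomes(self) -> tuple[WeightedGraph, ...]:
        return (self.after, *self.alternates)


def fig_micro_cases() -> list[MicroCase]:
    """Exact single-step before/after configurations for each null model.

    The rich-club and mixing cases include anchor edges through extra
    nodes, arranged so that the intended move is the *only* valid one: any
    other edge pair either shares an endpoint or targets an existing
    edge.  This makes a one-swap run deterministic up to the documented
    outcome set.
    """
    cases: list[MicroCase] = []

    # degree-preserving double edge swap: AB, CD -> AD, BC (weights travel)
    cases.append(
        MicroCase(
            name="one_k",
            before=WeightedGraph([("A", "B", 3), ("C", "D", 2)]),
            after=WeightedGraph([("A", "D", 3), ("B", "C", 2)]),
            alternates=(
                WeightedGraph([("A", "D", 2), ("B", "C", 3)]),
                WeightedGraph([("A", "C", 3), ("B", "D", 2)]),
                WeightedGraph([("A", "C", 2), ("B", "D", 3)]),
            ),
        )
    )

    # structure-shuffling: only equal-weight pairs swap, strengths intact
    cases.append(
        MicroCase(
            name="structure",
            before=WeightedGraph([("A", "B", 2), ("C", "D", 2)]),
            after=WeightedGraph([("A", "D", 2), ("B", "C", 2)]),
            alternates=(WeightedGraph([("A", "C", 2), ("B", "D", 2)]),),
        )
    )

    # weight-shuffling: topology fixed, the two weights trade places
    cases.append(
        MicroCase(
            name="weight",
            before=WeightedGraph([("A", "B", 3), ("C", "D", 2)]),
            after=WeightedGraph([("A", "B", 2), ("C", "D", 3)]),
        )
    )

    # rich-club construction: rich pair (A, B) gains its edge at the
    # expense of edges to non-rich neighbors C and D.  R anchors A and B
    # at the top of the strength ranking; rich set = {R, A, B}.
    cases.append(
        MicroCase(
            name="rich_club_enhance",
            before=WeightedGraph(
                [("A", "R", 10), ("B", "R", 9), ("A", "C", 2), ("B", "D", 1)]
            ),
            after=WeightedGraph(
                [("A", "R", 10), ("B", "R", 9), ("A", "B", 2), ("C", "D", 1)]
            ),
            params={"rich_fraction": 0.5},
        )
    )

    # strength-mixing moves on edges AC, BD with strengths A > D > C > B.
    # Anchor edges through hub H block every other edge pair.
    mixing_before = WeightedGraph(
        [
            ("A", "C", 4),
            ("B", "D", 2),
            ("A", "H", 6),
            ("D", "H", 4),
            ("C", "H", 1),
            ("B", "H", 1),
        ]
    )
    anchors = [("A", "H", 6), ("D", "H", 4), ("C", "H", 1), ("B", "H", 1)]
    cases.append(
        MicroCase(
            name="assortative",
            before=mixing_before,
            after=WeightedGraph([("A", "D", 4), ("B", "C", 2), *anchors]),
        )
    )
    cases.append(
        MicroCase(
            name="disassortative",
            before=mixing_before.copy(),
            after=WeightedGraph([("A", "B", 4), ("C", "D", 2), *anchors]),
        )
    )
    return cases
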