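"""Randomized surrogate (null-model) constructions for weighted networks.

A null model scrambles selected features of a network while conserving
others; comparing link-prediction accuracy on the original network against
its nulls quantifies how much the scrambled feature contributes.  Five
rewiring constructions are provided:

=====================  ===========================================  =================================
operation              randomizes                                   conserves
=====================  ===========================================  =================================
:func:`rewire_1k`      topology and weight placement                degree sequence, weight multiset
:func:`shuffle_structure`  topology (equal-weight edge swaps)       degree sequence, every strength
:func:`shuffle_weights`    weight placement                         the entire edge set
:func:`rewire_rich_club`   density of links inside the rich club    degree sequence, weight multiset
:func:`rewire_assortativity`  strength mixing pattern               degree sequence, weight multiset
=====================  ===========================================  =================================

All operations return a :class:`NullModelReport` carrying a *new* graph
(inputs are never mutated) plus swap counters and conservation
diagnostics.  ``n_swaps`` counts successful swaps; rejection sampling is
bounded by an attempt budget of ``100 × n_swaps``, after which a partial
randomization is returned with a warning recorded in the report.

The elementary move is the double edge swap: edges (A,B) and (C,D) with
four distinct endpoints are replaced by (A,D) and (B,C), provided neither
replacement already exists, so the graph stays simple and every node keeps
its degree.  The weight of each removed edge travels with its first
endpoint: (A,D) inherits w(A,B) and (B,C) inherits w(C,D), which conserves
the multiset of edge weights.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph_core import Edge, WeightedGraph, canonical_edge

__all__ = [
    "NullKind",
    "NullModelReport",
    "RichClubSpec",
    "ATTEMPT_FACTOR",
    "rewire_1k",
    "rewire_1k_subset",
    "shuffle_structure",
    "shuffle_weights",
    "rewire_rich_club",
    "rewire_assortativity",
    "rich_club_coefficient",
    "rich_club_spec",
    "strength_assortativity",
]

#: Attempt budget multiplier for all rejection-sampling loops.
ATTEMPT_FACTOR = 100


class NullKind(str, enum.Enum):
    ONE_K = "1k"
    STRUCTURE = "structure"
    WEIGHT = "weight"
    RICH_CLUB_ENHANCE = "rich_club_enhance"
    RICH_CLUB_DESTROY = "rich_club_destroy"
    ASSORTATIVE = "assortative"
    DISASSORTATIVE = "disassortative"


@dataclass
class NullModelReport:
    """Outcome of one null-model construction run."""

    graph: WeightedGraph
    kind: NullKind
    seed: int
    target: int
    attempted: int
    succeeded: int
    warnings: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def conservation(self, original: WeightedGraph) -> dict[str, bool]:
        """Diagnostics comparing the null graph against the original."""
        g = self.graph
        checks = {
            "node_set": g.nodes == original.nodes,
            "edge_count": g.n_edges == original.n_edges,
            "degree_sequence": g.degree_sequence() == original.degree_sequence(),
            "total_weight": math.isclose(
                g.total_weight, original.total_weight, rel_tol=1e-9
            ),
            "weight_multiset": g.weight_multiset() == original.weight_multiset(),
        }
        return checks

    def to_json(self, original: WeightedGraph | None = None) -> str:
        payload = {
            "kind": self.kind.value,
            "seed": self.seed,
            "target": self.target,
            "attempted": self.attempted,
            "succeeded": self.succeeded,
            "warnings": list(self.warnings),
            "extras": {k: v for k, v in self.extras.items()},
        }
        if original is not None:
            payload["conservation"] = self.conservation(original)
        return json.dumps(payload, indent=2, default=float)


@dataclass(frozen=True)
class RichClubSpec:
    """The designated rich set of a graph and its realized club density."""

    rich_fraction: float
    rich_nodes: frozenset[str]
    coefficient: float


# ---------------------------------------------------------------------------
# internal helpers


class _EdgePool:
    """Mutable edge list with O(1) uniform sampling and replacement."""

    def __init__(self, edges: list[Edge]):
        self.order: list[Edge] = list(edges)
        self.pos: dict[Edge, int] = {e: i for i, e in enumerate(self.order)}

    def __len__(self) -> int:
        return len(self.order)

    def __contains__(self, e: Edge) -> bool:
        return e in self.pos

    def sample(self, rng: np.random.Generator) -> Edge:
        return self.order[rng.integers(len(self.order))]

    def sample_two(self, rng: np.random.Generator) -> tuple[Edge, Edge]:
        i = int(rng.integers(len(self.order)))
        j = int(rng.integers(len(self.order) - 1))
        if j >= i:
            j += 1
        return self.order[i], self.order[j]

    def remove(self, e: Edge) -> None:
        i = self.pos.pop(e)
        last = self.order.pop()
        if last != e:
            self.order[i] = last
            self.pos[last] = i

    def add(self, e: Edge) -> None:
        self.pos[e] = len(self.order)
        self.order.append(e)


def _orient(edge: Edge, rng: np.random.Generator) -> tuple[str, str]:
    """Random orientation of an undirected edge."""
    return edge if rng.integers(2) == 0 else (edge[1], edge[0])


def _default_swaps(graph: WeightedGraph, n_swaps: int | None) -> int:
    if n_swaps is None:
        return 2 * graph.n_edges
    if n_swaps < 0:
        raise ValueError("n_swaps must be nonnegative")
    return n_swaps


# ---------------------------------------------------------------------------
# 1k (degree-preserving) randomization


def rewire_1k(
    graph: WeightedGraph, n_swaps: int | None = None, rng_seed: int = 0
) -> NullModelReport:
    """Degree-preserving randomization by repeated double edge swaps.

    Destroys both the topology correlations and the weight–topology
    correlation of the input while conserving the degree of every node and
    the multiset of edge weights.  The default number of successful swaps
    is twice the number of edges, enough to decorrelate the edge set.
    """
    return _rewire_1k_engine(graph, None, n_swaps, rng_seed, NullKind.ONE_K)


def rewire_1k_subset(
    graph: WeightedGraph,
    subset: set[Edge] | list[Edge],
    n_swaps: int | None = None,
    rng_seed: int = 0,
) -> NullModelReport:
    """1k randomization restricted to a designated edge subset.

    Both edges of every swap are drawn from the subset (tracked
    dynamically: replacement edges inherit subset membership), so edges
    outside the subset are bit-identical in the output.  Used to scramble
    only the strong ties, only the weak ties, or a random half.
    """
    subset = {canonical_edge(*e) for e in subset}
    missing = [e for e in subset if not graph.has_edge(*e)]
    if missing:
        raise ValueError(f"subset contains non-edges, e.g. {missing[0]}")
    if len(subset) < 2:
        raise ValueError("subset must contain at least 2 edges")
    return _rewire_1k_engine(graph, subset, n_swaps, rng_seed, NullKind.ONE_K)


def _rewire_1k_engine(
    graph: WeightedGraph,
    subset: set[Edge] | None,
    n_swaps: int | None,
    rng_seed: int,
    kind: NullKind,
) -> NullModelReport:
    pool_edges = sorted(subset) if subset is not None else graph.edge_list()
    n_swaps = 2 * len(pool_edges) if n_swaps is None else _default_swaps(graph, n_swaps)
    work = graph.copy()
    rng = np.random.default_rng(rng_seed)
    report = NullModelReport(
        graph=work, kind=kind, seed=rng_seed, target=n_swaps, attempted=0, succeeded=0
    )
    if len(pool_edges) < 2 or n_swaps == 0:
        if n_swaps > 0:
            report.warnings.append("graph too small to swap")
        return report

    pool = _EdgePool(pool_edges)
    budget = ATTEMPT_FACTOR * n_swaps
    while report.succeeded < n_swaps and report.attempted < budget:
        report.attempted += 1
        e1, e2 = pool.sample_two(rng)
        a, b = _orient(e1, rng)
        c, d = _orient(e2, rng)
        if len({a, b, c, d}) < 4:
            continue
        if work.has_edge(a, d) or work.has_edge(b, c):
            continue
        w1, w2 = work.weight(a, b), work.weight(c, d)
        work.remove_edge(a, b)
        work.remove_edge(c, d)
        work.add_edge(a, d, w1)
        work.add_edge(b, c, w2)
        pool.remove(e1)
        pool.remove(e2)
        pool.add(canonical_edge(a, d))
        pool.add(canonical_edge(b, c))
        report.succeeded += 1
    if report.succeeded < n_swaps:
        report.warnings.append(
            f"attempt budget exhausted: {report.succeeded}/{n_swaps} swaps done"
        )
    return report


# ---------------------------------------------------------------------------
# structure-shuffling (strength-preserving topology randomization)


class ShuffleMode(str, enum.Enum):
    EXACT = "exact"
    NEAREST = "nearest"


def shuffle_structure(
    graph: WeightedGraph,
    n_swaps: int | None = None,
    mode: ShuffleMode | str = ShuffleMode.EXACT,
    tolerance: float = 0.05,
    rng_seed: int = 0,
) -> NullModelReport:
    """Randomize topology while preserving each node's weight environment.

    In ``EXACT`` mode only pairs of edges with exactly equal weight are
    endpoint-swapped; with the first-endpoint weight-carrying rule the
    strength of every node is then conserved exactly.  Networks whose
    weights are all distinct cannot be shuffled this way; ``NEAREST`` mode
    relaxes the constraint, pairing each drawn edge with the valid partner
    of closest weight and accepting the swap when the relative weight
    difference is at most ``tolerance``.  The resulting per-node strength
    drift is accumulated and reported in ``extras`` (each accepted swap
    perturbs exactly two nodes by |w1 − w2|).
    """
    mode = ShuffleMode(mode)
    n_swaps = _default_swaps(graph, n_swaps)
    work = graph.copy()
    rng = np.random.default_rng(rng_seed)
    report = NullModelReport(
        graph=work,
        kind=NullKind.STRUCTURE,
        seed=rng_seed,
        target=n_swaps,
        attempted=0,
        succeeded=0,
    )
    edges = work.edge_list()
    if len(edges) < 2 or n_swaps == 0:
        if n_swaps > 0:
            report.warnings.append("graph too small to swap")
        return report

    pool = _EdgePool(edges)
    # weight -> pool of edges at that exact weight (EXACT-mode partner lookup)
    groups: dict[float, _EdgePool] = {}
    for e in edges:
        groups.setdefault(work.weight(*e), _EdgePool([])).add(e)

    if mode is ShuffleMode.EXACT and all(len(g) < 2 for g in groups.values()):
        report.warnings.append("no two edges share a weight; nothing to shuffle")
        return report

    drift: dict[str, float] = {}
    budget = ATTEMPT_FACTOR * n_swaps
    while report.succeeded < n_swaps and report.attempted < budget:
        report.attempted += 1
        e1 = pool.sample(rng)
        w1 = work.weight(*e1)
        if mode is ShuffleMode.EXACT:
            grp = groups[w1]
            if len(grp) < 2:
                continue
            e2 = grp.sample(rng)
            if e2 == e1:
                continue
        else:
            e2 = _nearest_partner(work, pool, e1, rng)
            if e2 is None:
                continue
            w2 = work.weight(*e2)
            if abs(w1 - w2) > tolerance * max(w1, w2):
                continue
        a, b = _orient(e1, rng)
        c, d = _orient(e2, rng)
        if len({a, b, c, d}) < 4:
            continue
        if work.has_edge(a, d) or work.has_edge(b, c):
            continue
        w2 = work.weight(c, d)
        work.remove_edge(a, b)
        work.remove_edge(c, d)
        work.add_edge(a, d, w1)
        work.add_edge(b, c, w2)
        for e_old, e_new in ((e1, canonical_edge(a, d)), (e2, canonical_edge(b, c))):
            pool.remove(e_old)
            pool.add(e_new)
        groups[w1].remove(e1)
        groups[w2].remove(e2)
        groups[w1].add(canonical_edge(a, d))
        groups[w2].add(canonical_edge(b, c))
        if w1 != w2:
            # endpoints b and d trade w1 for w2
            drift[b] = drift.get(b, 0.0) + abs(w1 - w2)
            drift[d] = drift.get(d, 0.0) + abs(w1 - w2)
        report.succeeded += 1
    if report.succeeded < n_swaps:
        report.warnings.append(
            f"attempt budget exhausted: {report.succeeded}/{n_swaps} swaps done"
        )
    report.extras["strength_drift_max"] = max(drift.values(), default=0.0)
    report.extras["strength_drift_total"] = sum(drift.values())
    return report


def _nearest_partner(
    work: WeightedGraph, pool: _EdgePool, e1: Edge, rng: np.random.Generator
) -> Edge | None:
    """Valid swap partner of ``e1`` with the closest weight (ties random)."""
    w1 = work.weight(*e1)
    a, b = e1
    best: list[Edge] = []
    best_diff = math.inf
    for e2 in pool.order:
        if e2 == e1:
            continue
        c, d = e2
        if c in (a, b) or d in (a, b):
            continue
        # at least one of the two pairings must be free
        if (work.has_edge(a, d) or work.has_edge(b, c)) and (
            work.has_edge(a, c) or work.has_edge(b, d)
        ):
            continue
        diff = abs(work.weight(c, d) - w1)
        if diff < best_diff:
            best, best_diff = [e2], diff
        elif diff == best_diff:
            best.append(e2)
    if not best:
        return None
    return best[int(rng.integers(len(best)))]


# ---------------------------------------------------------------------------
# weight-shuffling (topology-preserving weight randomization)


def shuffle_weights(
    graph: WeightedGraph, n_swaps: int | None = None, rng_seed: int = 0
) -> NullModelReport:
    """Exchange weights between randomly chosen edge pairs on a fixed topology.

    Each step draws two edges with *different* weights and swaps their
    weights, scrambling the weight–topology correlation while leaving the
    edge set untouched.  With enough swaps the weight assignment converges
    to a uniform random permutation of the original weights over the
    original edges.
    """
    n_swaps = _default_swaps(graph, n_swaps)
    work = graph.copy()
    rng = np.random.default_rng(rng_seed)
    report = NullModelReport(
        graph=work,
        kind=NullKind.WEIGHT,
        seed=rng_seed,
        target=n_swaps,
        attempted=0,
        succeeded=0,
    )
    edges = work.edge_list()
    if len(edges) < 2 or n_swaps == 0:
        if n_swaps > 0:
            report.warnings.append("graph too small to swap")
        return report
    if len(set(work.weight(*e) for e in edges)) == 1:
        report.warnings.append("all weights equal; nothing to shuffle")
        return report

    pool = _EdgePool(edges)
    budget = ATTEMPT_FACTOR * n_swaps
    while report.succeeded < n_swaps and report.attempted < budget:
        report.attempted += 1
        e1, e2 = pool.sample_two(rng)
        w1, w2 = work.weight(*e1), work.weight(*e2)
        if w1 == w2:
            continue
        work.set_weight(*e1, w2)
        work.set_weight(*e2, w1)
        report.succeeded += 1
    if report.succeeded < n_swaps:
        report.warnings.append(
            f"attempt budget exhausted: {report.succeeded}/{n_swaps} swaps done"
        )
    return report


# ---------------------------------------------------------------------------
# rich-club construction / destruction


def _rich_set(graph: WeightedGraph, rich_fraction: float) -> list[str]:
    """Top ``ceil(rich_fraction·|V|)`` nodes by strength (ties by label)."""
    if not 0 < rich_fraction < 1:
        raise ValueError("rich_fraction must lie in (0, 1)")
    k = math.ceil(rich_fraction * graph.n_nodes)
    ranked = sorted(graph.nodes, key=lambda n: (-graph.strength(n), n))
    return ranked[:k]


def rich_club_coefficient(graph: WeightedGraph, rich_fraction: float = 0.05) -> float:
    """Density of edges inside the rich set: realized / possible rich pairs.

    Rich nodes are the top ``ceil(rich_fraction·|V|)`` nodes by strength.
    """
    rich = _rich_set(graph, rich_fraction)
    return _club_density(graph, set(rich))


def rich_club_spec(graph: WeightedGraph, rich_fraction: float = 0.05) -> RichClubSpec:
    rich = _rich_set(graph, rich_fraction)
    return RichClubSpec(
        rich_fraction=rich_fraction,
        rich_nodes=frozenset(rich),
        coefficient=_club_density(graph, set(rich)),
    )


def _club_density(graph: WeightedGraph, rich: set[str]) -> float:
    if len(rich) < 2:
        raise ValueError("rich set must contain at least 2 nodes")
    inside = sum(1 for x, y in graph.edges() if x in rich and y in rich)
    return inside / math.comb(len(rich), 2)


class RichClubDirection(str, enum.Enum):
    ENHANCE = "enhance"
    DESTROY = "destroy"


def rewire_rich_club(
    graph: WeightedGraph,
    rich_fraction: float = 0.05,
    direction: RichClubDirection | str = RichClubDirection.ENHANCE,
    max_iters: int | None = None,
    rng_seed: int = 0,
) -> NullModelReport:
    """Degree-preserving rewiring that builds up or tears down the rich club.

    The rich set — top ``ceil(rich_fraction·|V|)`` nodes by strength — is
    frozen at the start of the run (moves shift strengths, and re-ranking
    mid-run would make the target non-stationary).

    ``ENHANCE`` repeatedly picks an unconnected rich pair (A, B), a
    non-rich neighbor C of A and a non-rich neighbor D of B with C ≠ D and
    (C, D) absent, then replaces (A,C), (B,D) by (A,B), (C,D): each
    success adds exactly one rich–rich edge, so the club density is
    monotone non-decreasing.  ``DESTROY`` is the inverse move: a connected
    rich pair (A, B) and a connected non-rich pair (C, D) with (A,C) and
    (B,D) absent are rewired to (A,C), (B,D), removing one rich–rich edge
    per success.  The run stops at ``max_iters`` successes (default: run
    to saturation) or when no valid move remains.
    """
    direction = RichClubDirection(direction)
    rich = _rich_set(graph, rich_fraction)
    if len(rich) < 2:
        raise ValueError("rich set must contain at least 2 nodes")
    rich_set = set(rich)
    work = graph.copy()
    rng = np.random.default_rng(rng_seed)
    kind = (
        NullKind.RICH_CLUB_ENHANCE
        if direction is RichClubDirection.ENHANCE
        else NullKind.RICH_CLUB_DESTROY
    )

    pairs_possible = math.comb(len(rich), 2)
    inside0 = sum(1 for x, y in work.edges() if x in rich_set and y in rich_set)
    if direction is RichClubDirection.ENHANCE:
        saturation = pairs_possible - inside0
    else:
        saturation = inside0
    target = saturation if max_iters is None else min(max_iters, saturation)

    report = NullModelReport(
        graph=work, kind=kind, seed=rng_seed, target=target, attempted=0, succeeded=0
    )
    report.extras["rich_fraction"] = rich_fraction
    report.extras["rich_nodes"] = sorted(rich)
    report.extras["coefficient_before"] = inside0 / pairs_possible

    budget = ATTEMPT_FACTOR * max(target, 1)
    while report.succeeded < target and report.attempted < budget:
        report.attempted += 1
        if direction is RichClubDirection.ENHANCE:
            ok = _enhance_step(work, rich, rich_set, rng)
        else:
            ok = _destroy_step(work, rich, rich_set, rng)
        if ok is None:  # no valid move exists at all: saturated
            report.warnings.append("saturated: no valid move remains")
            break
        if ok:
            report.succeeded += 1
    if report.succeeded < target and not report.warnings:
        report.warnings.append(
            f"attempt budget exhausted: {report.succeeded}/{target} moves done"
        )
    inside1 = sum(1 for x, y in work.edges() if x in rich_set and y in rich_set)
    report.extras["coefficient_after"] = inside1 / pairs_possible
    return report


def _enhance_step(
    work: WeightedGraph, rich: list[str], rich_set: set[str], rng: np.random.Generator
) -> bool | None:
    """One attempted rich-club construction move.  None => saturated."""
    open_pairs = [
        (rich[i], rich[j])
        for i in range(len(rich))
        for j in range(i + 1, len(rich))
        if not work.has_edge(rich[i], rich[j])
    ]
    if not open_pairs:
        return None
    a, b = open_pairs[int(rng.integers(len(open_pairs)))]
    ca = sorted(z for z in work.neighbors(a) if z not in rich_set)
    db = sorted(z for z in work.neighbors(b) if z not in rich_set)
    if not ca or not db:
        return False
    c = ca[int(rng.integers(len(ca)))]
    d = db[int(rng.integers(len(db)))]
    if c == d or work.has_edge(c, d):
        return False
    w_ac, w_bd = work.weight(a, c), work.weight(b, d)
    work.remove_edge(a, c)
    work.remove_edge(b, d)
    work.add_edge(a, b, w_ac)
    work.add_edge(c, d, w_bd)
    return True


def _destroy_step(
    work: WeightedGraph, rich: list[str], rich_set: set[str], rng: np.random.Generator
) -> bool | None:
    """One attempted rich-club destruction move.  None => saturated."""
    club_edges = [e for e in work.edge_list() if e[0] in rich_set and e[1] in rich_set]
    if not club_edges:
        return None
    a, b = _orient(club_edges[int(rng.integers(len(club_edges)))], rng)
    poor_edges = [
        e for e in work.edge_list() if e[0] not in rich_set and e[1] not in rich_set
    ]
    if not poor_edges:
        return False
    c, d = _orient(poor_edges[int(rng.integers(len(poor_edges)))], rng)
    if work.has_edge(a, c) or work.has_edge(b, d):
        return False
    w_ab, w_cd = work.weight(a, b), work.weight(c, d)
    work.remove_edge(a, b)
    work.remove_edge(c, d)
    work.add_edge(a, c, w_ab)
    work.add_edge(b, d, w_cd)
    return True


# ---------------------------------------------------------------------------
# strength assortativity rewiring


class MixingDirection(str, enum.Enum):
    ASSORTATIVE = "assortative"
    DISASSORTATIVE = "disassortative"


def strength_assortativity(graph: WeightedGraph) -> float:
    """Pearson correlation of endpoint strengths over edges (symmetrized).

    Each edge contributes both orientations, so the statistic is
    orientation-free.  Raises if the endpoint strengths have zero
    variance (e.g. a regular graph with equal weights), where the
    correlation is undefined.
    """
    if graph.n_edges < 2:
        raise ValueError("need at least 2 edges")
    s = graph.strength_map()
    xs, ys = [], []
    for x, y in graph.edges():
        xs.extend((s[x], s[y]))
        ys.extend((s[y], s[x]))
    xa = np.asarray(xs, dtype=float)
    ya = np.asarray(ys, dtype=float)
    if np.ptp(xa) == 0:
        raise ValueError("endpoint strengths have zero variance; correlation undefined")
    return float(np.corrcoef(xa, ya)[0, 1])


def rewire_assortativity(
    graph: WeightedGraph,
    direction: MixingDirection | str = MixingDirection.ASSORTATIVE,
    n_swaps: int | None = None,
    rng_seed: int = 0,
) -> NullModelReport:
    """Bias the strength mixing pattern by targeted double edge swaps.

    Each step draws two edges with four distinct endpoints and ranks the
    endpoints by current strength (ties broken by label).  The
    ``ASSORTATIVE`` move reconnects rank 1 with rank 2 and rank 3 with
    rank 4 (strong-with-strong, weak-with-weak); ``DISASSORTATIVE``
    reconnects rank 1 with rank 4 and rank 2 with rank 3.  A move is
    applied only when both target edges are absent.  Each new edge
    inherits the weight of the removed edge that contained the new edge's
    higher-ranked endpoint; the partner edge takes the remaining weight,
    which keeps the weight multiset intact.  The drift of the strength
    assortativity is monitored over the run (carried weights shift
    strengths, so single steps are not individually guaranteed to move the
    statistic).
    """
    direction = MixingDirection(direction)
    n_swaps = _default_swaps(graph, n_swaps)
    work = graph.copy()
    rng = np.random.default_rng(rng_seed)
    kind = (
        NullKind.ASSORTATIVE
        if direction is MixingDirection.ASSORTATIVE
        else NullKind.DISASSORTATIVE
    )
    report = NullModelReport(
        graph=work, kind=kind, seed=rng_seed, target=n_swaps, attempted=0, succeeded=0
    )
    edges = work.edge_list()
    if len(edges) < 2 or n_swaps == 0:
        if n_swaps > 0:
            report.warnings.append("graph too small to swap")
        return report
    try:
        report.extras["assortativity_before"] = strength_assortativity(graph)
    except ValueError:
        report.extras["assortativity_before"] = None

    # strengths maintained incrementally; recomputing per attempt is O(E)
    s = work.strength_map()
    pool = _EdgePool(edges)
    budget = ATTEMPT_FACTOR * n_swaps
    while report.succeeded < n_swaps and report.attempted < budget:
        report.attempted += 1
        e1, e2 = pool.sample_two(rng)
        nodes = {*e1, *e2}
        if len(nodes) < 4:
            continue
        ranked = sorted(nodes, key=lambda n: (-s[n], n))
        if direction is MixingDirection.ASSORTATIVE:
            t1, t2 = (ranked[0], ranked[1]), (ranked[2], ranked[3])
        else:
            t1, t2 = (ranked[0], ranked[3]), (ranked[1], ranked[2])
        if work.has_edge(*t1) or work.has_edge(*t2):
            continue
        w1, w2 = work.weight(*e1), work.weight(*e2)
        # t1 contains the globally top-ranked endpoint; it inherits the
        # weight of the removed edge that endpoint belonged to
        w_t1 = w1 if ranked[0] in e1 else w2
        w_t2 = w2 if ranked[0] in e1 else w1
        work.remove_edge(*e1)
        work.remove_edge(*e2)
        work.add_edge(*t1, w_t1)
        work.add_edge(*t2, w_t2)
        for n in e1:
            s[n] -= w1
        for n in e2:
            s[n] -= w2
        for n in t1:
            s[n] += w_t1
        for n in t2:
            s[n] += w_t2
        pool.remove(e1)
        pool.remove(e2)
        pool.add(canonical_edge(*t1))
        pool.add(canonical_edge(*t2))
        report.succeeded += 1
    if report.succeeded < n_swaps:
        report.warnings.append(
            f"attempt budget exhausted: {report.succeeded}/{n_swaps} swaps done"
        )
    try:
        report.extras["assortativity_after"] = strength_assortativity(work)
    except ValueError:
        report.extras["assortativity_after"] = None
    return report
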