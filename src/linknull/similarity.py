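"""Local similarity indices for link prediction in weighted networks.

Six common-neighbor indices are provided.  For a candidate pair (x, y)
with common-neighbor set ``Γ(x) ∩ Γ(y)``:

* ``CN``  — number of common neighbors, ``|Γ(x) ∩ Γ(y)|``;
* ``AA``  — Adamic–Adar, ``Σ_z 1 / log k(z)``;
* ``RA``  — resource allocation, ``Σ_z 1 / k(z)``;
* ``WCN`` — weighted CN, ``Σ_z (w(x,z)^α + w(z,y)^α)``;
* ``WAA`` — weighted AA, ``Σ_z (w(x,z)^α + w(z,y)^α) / log(1 + s(z))``;
* ``WRA`` — weighted RA, ``Σ_z (w(x,z)^α + w(z,y)^α) / s(z)``.

The exponent α tunes the role of weights: α > 0 amplifies heavy (strong)
ties, α < 0 amplifies light (weak) ties, and α = 0 removes the weight
dependence of each numerator term — ``WCN(α=0) = 2·CN`` exactly.

Logarithms are natural.  The choice of base rescales AA scores by a
constant factor and WAA scores by a constant factor, so rankings — and
hence AUC and Precision — are unaffected.

A common neighbor z of x and y is adjacent to both, so k(z) ≥ 2 always
holds (even on a training graph after edge removal) and ``log k(z)`` never
vanishes; this is asserted rather than special-cased.  Weights are
validated positive at load time, so ``w^α`` with α < 0 never divides by
zero and ``s(z) > 0`` for any node with an edge.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .graph_core import Edge, WeightedGraph, canonical_edge

__all__ = ["INDEX_NAMES", "IndexSpec", "ScoreTable", "score_pair", "score_candidates"]

#: The six supported index names.  The W* forms take the exponent α.
INDEX_NAMES = ("CN", "AA", "RA", "WCN", "WAA", "WRA")

_WEIGHTED = frozenset({"WCN", "WAA", "WRA"})


@dataclass(frozen=True)
class IndexSpec:
    """A similarity index selection: name plus weight exponent α.

    ``alpha`` is ignored for the unweighted indices CN, AA, RA.
    """

    name: str
    alpha: float = 1.0

    def __post_init__(self):
        if self.name not in INDEX_NAMES:
            raise ValueError(f"unknown index {self.name!r}; expected one of {INDEX_NAMES}")

    @property
    def weighted(self) -> bool:
        return self.name in _WEIGHTED

    def label(self) -> str:
        return f"{self.name}(alpha={self.alpha:g})" if self.weighted else self.name


@dataclass
class ScoreTable:
    """Similarity scores for a batch of candidate pairs under one index.

    Keys are canonical (sorted) node pairs; scores are nonnegative and
    symmetric by construction.
    """

    scores: dict[Edge, float]
    index: IndexSpec

    def __len__(self) -> int:
        return len(self.scores)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return self.scores[canonical_edge(*pair)]

    def to_csv(self, path: str | Path) -> None:
        """Export as CSV with columns node_x, node_y, score, index, alpha."""
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["node_x", "node_y", "score", "index", "alpha"])
            for (x, y) in sorted(self.scores):
                writer.writerow([x, y, repr(self.scores[(x, y)]), self.index.name, self.index.alpha])


def score_pair(graph: WeightedGraph, x: str, y: str, index: IndexSpec) -> float:
    """Similarity score S_xy of one candidate pair against ``graph``.

    Common neighbors, degrees, strengths, and weights are all taken from
    the supplied graph; in an evaluation protocol this is the training
    graph, with probe edges invisible.
    """
    if x == y:
        raise ValueError(f"cannot score a self-pair ({x!r}, {x!r})")
    if x not in graph:
        raise ValueError(f"node {x!r} not in graph")
    if y not in graph:
        raise ValueError(f"node {y!r} not in graph")

    common = graph.neighbors(x) & graph.neighbors(y)
    if not common:
        return 0.0

    name, alpha = index.name, index.alpha
    if name == "CN":
        return float(len(common))
    if name == "AA":
        total = 0.0
        for z in common:
            kz = graph.degree(z)
            assert kz >= 2, "a common neighbor is adjacent to both endpoints"
            total += 1.0 / math.log(kz)
        return total
    if name == "RA":
        return sum(1.0 / graph.degree(z) for z in common)

    # weighted forms share the (w(x,z)^α + w(z,y)^α) numerator
    total = 0.0
    for z in common:
        num = graph.weight(x, z) ** alpha + graph.weight(z, y) ** alpha
        if name == "WCN":
            total += num
        elif name == "WAA":
            total += num / math.log1p(graph.strength(z))
        else:  # WRA
            total += num / graph.strength(z)
    return total


def score_candidates(
    graph: WeightedGraph,
    pairs: Iterable[tuple[str, str]],
    index: IndexSpec,
) -> ScoreTable:
    """Score a batch of candidate pairs; duplicate orientations collapse.

    The result has one entry per distinct unordered pair.
    """
    scores: dict[Edge, float] = {}
    for x, y in pairs:
        key = canonical_edge(str(x), str(y))
        if key not in scores:
            scores[key] = score_pair(graph, key[0], key[1], index)
    return ScoreTable(scores=scores, index=index)
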