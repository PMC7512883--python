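"""Weighted-graph data model, derived node statistics, and file formats.

The central container is :class:`WeightedGraph`, a thin validating wrapper
around an undirected simple :class:`networkx.Graph` whose edges carry
positive real weights.  Node labels are opaque strings: numeric labels in
input files are *not* coerced to integers, which keeps identity stable
across the edge-list and Pajek formats.

Two plain-text formats are supported:

* weighted edge lists — one ``node node weight`` triple per line,
  whitespace- or tab-delimited, ``#`` comments allowed;
* Pajek ``.net`` files — ``*Vertices`` / ``*Edges`` / ``*Arcs`` sections
  with 1-based indices, optional quoted labels, and an optional trailing
  weight (default 1.0).
"""

from __future__ import annotations

import math
import shlex
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "WeightedGraph",
    "NodeStats",
    "GraphFormatError",
    "GraphValidationError",
    "canonical_edge",
    "read_edgelist",
    "write_edgelist",
    "read_pajek",
    "write_pajek",
    "node_stats",
]


class GraphValidationError(ValueError):
    """An edge or weight violates the weighted-graph invariants."""


class GraphFormatError(ValueError):
    """A file could not be parsed as the advertised format."""


Edge = tuple[str, str]


def canonical_edge(x: str, y: str) -> Edge:
    """Canonical (sorted) form of an undirected edge key."""
    return (x, y) if x <= y else (y, x)


class WeightedGraph:
    """Undirected simple graph with positive edge weights.

    Invariants enforced on construction and on every mutation:

    * no self-loops;
    * no parallel edges (adding an existing edge is an error);
    * every weight is a positive, finite real.

    Null-model operations never mutate their input; they work on a
    :meth:`copy` and return the new graph.
    """

    __slots__ = ("_g",)

    def __init__(self, edges: Iterable[tuple[str, str, float]] = (), nodes: Iterable[str] = ()):
        self._g = nx.Graph()
        for n in nodes:
            self._g.add_node(str(n))
        for x, y, w in edges:
            self.add_edge(str(x), str(y), w)

    # -- construction / mutation ------------------------------------------

    def add_node(self, x: str) -> None:
        self._g.add_node(str(x))

    def add_edge(self, x: str, y: str, weight: float) -> None:
        x, y = str(x), str(y)
        if x == y:
            raise GraphValidationError(f"self-loop on node {x!r}")
        if self._g.has_edge(x, y):
            raise GraphValidationError(f"duplicate edge ({x!r}, {y!r})")
        w = float(weight)
        if not math.isfinite(w) or w <= 0:
            raise GraphValidationError(f"non-positive weight {weight!r} on edge ({x!r}, {y!r})")
        self._g.add_edge(x, y, weight=w)

    def remove_edge(self, x: str, y: str) -> None:
        if not self._g.has_edge(x, y):
            raise GraphValidationError(f"no edge ({x!r}, {y!r}) to remove")
        self._g.remove_edge(x, y)

    def set_weight(self, x: str, y: str, weight: float) -> None:
        if not self._g.has_edge(x, y):
            raise GraphValidationError(f"no edge ({x!r}, {y!r})")
        w = float(weight)
        if not math.isfinite(w) or w <= 0:
            raise GraphValidationError(f"non-positive weight {weight!r}")
        self._g[x][y]["weight"] = w

    def copy(self) -> "WeightedGraph":
        g = WeightedGraph()
        g._g = self._g.copy()
        return g

    # -- queries -----------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> Iterator[Edge]:
        for x, y in self._g.edges:
            yield canonical_edge(x, y)

    def edge_list(self) -> list[Edge]:
        """Edges in deterministic lexicographic order."""
        return sorted(self.edges())

    def has_edge(self, x: str, y: str) -> bool:
        return self._g.has_edge(x, y)

    def weight(self, x: str, y: str) -> float:
        try:
            return self._g[x][y]["weight"]
        except KeyError:
            raise GraphValidationError(f"no edge ({x!r}, {y!r})") from None

    def neighbors(self, x: str) -> set[str]:
        if x not in self._g:
            raise GraphValidationError(f"unknown node {x!r}")
        return set(self._g[x])

    def degree(self, x: str) -> int:
        if x not in self._g:
            raise GraphValidationError(f"unknown node {x!r}")
        return self._g.degree(x)

    def strength(self, x: str) -> float:
        """Weighted degree s(x) = sum of incident edge weights."""
        if x not in self._g:
            raise GraphValidationError(f"unknown node {x!r}")
        return sum(d["weight"] for d in self._g[x].values())

    @property
    def total_weight(self) -> float:
        return sum(d["weight"] for _, _, d in self._g.edges(data=True))

    def weight_multiset(self) -> list[float]:
        return sorted(d["weight"] for _, _, d in self._g.edges(data=True))

    def degree_sequence(self) -> dict[str, int]:
        return dict(self._g.degree())

    def strength_map(self) -> dict[str, float]:
        return {x: self.strength(x) for x in self._g.nodes}

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    # -- dunder ------------------------------------------------------------

    def __contains__(self, x: str) -> bool:
        return x in self._g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedGraph):
            return NotImplemented
        if self.nodes != other.nodes or self.n_edges != other.n_edges:
            return False
        return all(
            other.has_edge(x, y) and other.weight(x, y) == self.weight(x, y)
            for x, y in self.edges()
        )

    def __hash__(self):  # mutable container
        raise TypeError("WeightedGraph is unhashable")

    def __repr__(self) -> str:
        return f"WeightedGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class NodeStats:
    """Derived per-node statistics of a weighted graph.

    ``degree[x] == len(neighbors[x])`` and
    ``strength[x] == sum(w(x, z) for z in neighbors[x])`` always hold.
    """

    degree: dict[str, int]
    strength: dict[str, float]
    neighbors: dict[str, set[str]]


def node_stats(graph: WeightedGraph) -> NodeStats:
    """Compute degree k(x), strength s(x), and neighbor sets for all nodes."""
    return NodeStats(
        degree=graph.degree_sequence(),
        strength=graph.strength_map(),
        neighbors={x: graph.neighbors(x) for x in graph.nodes},
    )


# ---------------------------------------------------------------------------
# Weighted edge lists


def read_edgelist(path: str | Path, delimiter: str | None = None) -> WeightedGraph:
    """Read a weighted edge list: ``source target weight`` per line.

    Lines starting with ``#`` and blank lines are skipped.  A duplicate
    edge (in either orientation) is an error rather than a silent merge,
    as is a self-loop or a non-positive weight.

    ``# isolated: <node>`` comment lines (written by :func:`write_edgelist`)
    re-create degree-zero nodes, so the writer/reader pair is an exact
    inverse even for graphs with isolated nodes.
    """
    graph = WeightedGraph()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                if line.startswith("# isolated:"):
                    graph.add_node(line[len("# isolated:"):].strip())
                continue
            fields = line.split(delimiter) if delimiter else line.split()
            if len(fields) < 3:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 'node node weight', got {line!r}"
                )
            x, y = fields[0], fields[1]
            try:
                w = float(fields[2])
            except ValueError:
                raise GraphFormatError(
                    f"{path}:{lineno}: weight {fields[2]!r} is not a number"
                ) from None
            try:
                graph.add_edge(x, y, w)
            except GraphValidationError as exc:
                raise GraphValidationError(f"{path}:{lineno}: {exc}") from None
    return graph


def write_edgelist(graph: WeightedGraph, path: str | Path) -> None:
    """Write a weighted edge list in lexicographic edge order.

    Weights are written with ``repr`` so that a round trip through
    :func:`read_edgelist` reproduces the graph bit-exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for x, y in graph.edge_list():
            fh.write(f"{x}\t{y}\t{graph.weight(x, y)!r}\n")
        isolated = sorted(n for n in graph.nodes if graph.degree(n) == 0)
        for n in isolated:
            fh.write(f"# isolated: {n}\n")


# ---------------------------------------------------------------------------
# Pajek .net


def read_pajek(path: str | Path) -> WeightedGraph:
    """Read a Pajek ``.net`` file into a :class:`WeightedGraph`.

    1-based vertex indices are mapped to their quoted labels, or to the
    stringified index when no label is given.  ``*Arcs`` pairs are
    symmetrized: the pair ``1 2`` and its mirror ``2 1`` collapse to a
    single undirected edge provided their weights agree (a mismatch is an
    error).  A missing weight column defaults to 1.0.
    """
    labels: dict[int, str] = {}
    n_vertices = 0
    graph = WeightedGraph()
    # arcs seen so far, canonical key -> weight (for symmetric-duplicate check)
    seen: dict[Edge, tuple[float, bool]] = {}  # (weight, was_arc)
    section = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if low.startswith("*vertices"):
                parts = line.split()
                if len(parts) < 2 or not parts[1].isdigit():
                    raise GraphFormatError(f"{path}:{lineno}: malformed *Vertices header")
                n_vertices = int(parts[1])
                section = "vertices"
                continue
            if low.startswith("*edges"):
                section = "edges"
                continue
            if low.startswith("*arcs"):
                section = "arcs"
                continue
            if low.startswith("*"):
                section = "other"
                continue

            if section == "vertices":
                try:
                    parts = shlex.split(line)
                except ValueError:
                    raise GraphFormatError(f"{path}:{lineno}: unbalanced quotes") from None
                if not parts or not parts[0].isdigit():
                    raise GraphFormatError(f"{path}:{lineno}: malformed vertex line {line!r}")
                idx = int(parts[0])
                if not 1 <= idx <= n_vertices:
                    raise GraphFormatError(
                        f"{path}:{lineno}: vertex index {idx} outside 1..{n_vertices}"
                    )
                labels[idx] = parts[1] if len(parts) > 1 else str(idx)
            elif section in ("edges", "arcs"):
                parts = line.split()
                if len(parts) < 2:
                    raise GraphFormatError(f"{path}:{lineno}: malformed edge line {line!r}")
                try:
                    i, j = int(parts[0]), int(parts[1])
                except ValueError:
                    raise GraphFormatError(f"{path}:{lineno}: non-integer vertex index") from None
                for idx in (i, j):
                    if not 1 <= idx <= n_vertices:
                        raise GraphFormatError(
                            f"{path}:{lineno}: vertex index {idx} outside 1..{n_vertices}"
                        )
                w = 1.0
                if len(parts) >= 3:
                    try:
                        w = float(parts[2])
                    except ValueError:
                        raise GraphFormatError(
                            f"{path}:{lineno}: weight {parts[2]!r} is not a number"
                        ) from None
                u = labels.get(i, str(i))
                v = labels.get(j, str(j))
                key = canonical_edge(u, v)
                if key in seen:
                    prev_w, prev_arc = seen[key]
                    if section == "arcs" and prev_arc:
                        # mirror arc: collapses onto the same undirected edge
                        if prev_w != w:
                            raise GraphFormatError(
                                f"{path}:{lineno}: arc ({i},{j}) weight {w} conflicts "
                                f"with its mirror's weight {prev_w}"
                            )
                        continue
                    raise GraphValidationError(f"{path}:{lineno}: duplicate edge ({u!r}, {v!r})")
                try:
                    graph.add_edge(u, v, w)
                except GraphValidationError as exc:
                    raise GraphValidationError(f"{path}:{lineno}: {exc}") from None
                seen[key] = (w, section == "arcs")
    # vertices declared but never referenced by an edge become isolated nodes
    for idx in range(1, n_vertices + 1):
        graph.add_node(labels.get(idx, str(idx)))
    return graph


def write_pajek(graph: WeightedGraph, path: str | Path) -> None:
    """Write a Pajek ``.net`` file (sorted labels, 1-based indices)."""
    order = sorted(graph.nodes)
    index = {n: i + 1 for i, n in enumerate(order)}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"*Vertices {len(order)}\n")
        for n in order:
            fh.write(f'{index[n]} "{n}"\n')
        fh.write("*Edges\n")
        for x, y in graph.edge_list():
            fh.write(f"{index[x]} {index[y]} {graph.weight(x, y)!r}\n")
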