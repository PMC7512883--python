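"""Strong/weak tie partitioning and subset-restricted randomization.

Edges ranked by weight split into a *strong* upper half and a *weak* lower
half.  Scrambling only one half with the degree-preserving 1k move (see
:func:`linknull.null_models.rewire_1k_subset`) and measuring the drop in
link-prediction accuracy attributes predictive signal to that half: the
"strong effect of weak ties" appears when scrambling the weak half hurts
most.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import Edge, WeightedGraph
from .null_models import NullModelReport, rewire_1k_subset

__all__ = ["TiePartition", "partition_strong_weak", "random_half", "rewire_1k_subset"]


@dataclass(frozen=True)
class TiePartition:
    """A 50/50 split of the edge set by descending weight.

    ``threshold_weight`` is the weight at the boundary (the smallest
    strong-tie weight).  When several edges share the boundary weight the
    tie class is split at random, so the threshold is exact only when no
    weight class straddles the median.
    """

    strong: frozenset[Edge]
    weak: frozenset[Edge]
    threshold_weight: float

    def __post_init__(self):
        if self.strong & self.weak:
            raise ValueError("strong and weak overlap")


def partition_strong_weak(graph: WeightedGraph, rng_seed: int = 0) -> TiePartition:
    """Split edges into strong (heavier) and weak (lighter) halves.

    Edges are sorted by weight descending; the first ``ceil(|E|/2)`` are
    strong (an odd edge count gives strong the extra edge).  Edges tied at
    the boundary weight are assigned uniformly at random under
    ``rng_seed``, so repeated experiments sample the boundary fairly.
    """
    edges = graph.edge_list()
    if len(edges) < 2:
        raise ValueError("need at least 2 edges to partition")
    rng = np.random.default_rng(rng_seed)
    n_strong = (len(edges) + 1) // 2

    by_weight = sorted(edges, key=lambda e: -graph.weight(*e))
    cut_w = graph.weight(*by_weight[n_strong - 1])
    above = [e for e in edges if graph.weight(*e) > cut_w]
    boundary = [e for e in edges if graph.weight(*e) == cut_w]
    take = n_strong - len(above)
    picked = rng.permutation(len(boundary))[:take]
    strong = set(above) | {boundary[i] for i in picked}
    weak = set(edges) - strong
    return TiePartition(
        strong=frozenset(strong), weak=frozenset(weak), threshold_weight=cut_w
    )


def random_half(graph: WeightedGraph, rng_seed: int = 0) -> frozenset[Edge]:
    """Uniformly random subset of ``floor(|E|/2)`` edges."""
    edges = graph.edge_list()
    if len(edges) < 2:
        raise ValueError("need at least 2 edges")
    rng = np.random.default_rng(rng_seed)
    k = len(edges) // 2
    idx = rng.choice(len(edges), size=k, replace=False)
    return frozenset(edges[i] for i in idx)
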