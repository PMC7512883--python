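import math

import numpy as np
import pytest
from scipy import stats

from linknull import (
    WeightedGraph,
    fig_micro_cases,
    rewire_1k,
    rewire_assortativity,
    rewire_rich_club,
    rich_club_coefficient,
    rich_club_spec,
    shuffle_structure,
    shuffle_weights,
    strength_assortativity,
)
from conftest import make_graph


def assert_conserved(original, null):
    assert null.nodes == original.nodes
    assert null.n_edges == original.n_edges
    assert null.degree_sequence() == original.degree_sequence()
    assert null.weight_multiset() == original.weight_multiset()


class TestRewire1k:
    def test_zero_swaps_is_identity(self):
        g = make_graph(0)
        report = rewire_1k(g, n_swaps=0, rng_seed=1)
        assert report.graph == g and report.succeeded == 0

    def test_input_never_mutated(self):
        g = make_graph(0)
        before = g.copy()
        rewire_1k(g, rng_seed=1)
        assert g == before

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_conservation(self, seed):
        g = make_graph(seed)
        report = rewire_1k(g, rng_seed=seed + 10)
        assert_conserved(g, report.graph)
        assert report.succeeded == report.target == 2 * g.n_edges

    def test_default_target_is_twice_edge_count(self):
        g = make_graph(3)
        assert rewire_1k(g, rng_seed=0).target == 2 * g.n_edges

    def test_determinism(self):
        g = make_graph(1)
        a = rewire_1k(g, rng_seed=42)
        b = rewire_1k(g, rng_seed=42)
        assert a.graph == b.graph and a.attempted == b.attempted

    def test_four_cycle_stays_simple_two_regular(self):
        cyc = WeightedGraph(
            [("A", "B", 1), ("B", "C", 2), ("C", "D", 3), ("D", "A", 4)]
        )
        report = rewire_1k(cyc, n_swaps=50, rng_seed=5)
        g = report.graph
        assert g.n_edges == 4
        assert all(g.degree(x) == 2 for x in "ABCD")
        assert sorted(g.weight_multiset()) == [1, 2, 3, 4]

    def test_too_small_graph(self):
        g = WeightedGraph([("A", "B", 1)])
        report = rewire_1k(g, n_swaps=5, rng_seed=0)
        assert report.succeeded == 0 and report.warnings


class TestShuffleStructure:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_exact_mode_preserves_every_strength(self, seed):
        g = make_graph(seed)  # integer weights: plenty of equal pairs
        report = shuffle_structure(g, mode="exact", rng_seed=seed)
        assert report.graph.strength_map() == g.strength_map()
        assert_conserved(g, report.graph)
        assert report.succeeded > 0

    def test_exact_mode_actually_moves_topology(self):
        g = make_graph(2)
        report = shuffle_structure(g, mode="exact", rng_seed=7)
        assert set(report.graph.edges()) != set(g.edges())

    def test_all_distinct_weights_cannot_shuffle(self):
        g = WeightedGraph([("A", "B", 1), ("C", "D", 2), ("E", "F", 3)])
        report = shuffle_structure(g, mode="exact", rng_seed=0)
        assert report.succeeded == 0
        assert report.graph == g
        assert any("share a weight" in w for w in report.warnings)

    def test_uniform_weights_behave_like_1k(self):
        g = WeightedGraph([(x, y, 1.0) for x, y in make_graph(4, n=100).edges()])
        report = shuffle_structure(g, mode="exact", rng_seed=3)
        assert report.succeeded == report.target
        assert_conserved(g, report.graph)
        assert set(report.graph.edges()) != set(g.edges())

    def test_nearest_mode_bounds_strength_drift(self):
        g = make_graph(5, discrete=False)
        tol = 0.05
        report = shuffle_structure(g, mode="nearest", tolerance=tol, rng_seed=1)
        assert_conserved(g, report.graph)
        drift_max = report.extras["strength_drift_max"]
        worst = max(
            abs(report.graph.strength(x) - g.strength(x)) for x in g.nodes
        )
        assert worst <= drift_max + 1e-9

    def test_determinism(self):
        g = make_graph(1)
        assert (
            shuffle_structure(g, rng_seed=9).graph
            == shuffle_structure(g, rng_seed=9).graph
        )


class TestShuffleWeights:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_topology_identical(self, seed):
        g = make_graph(seed)
        report = shuffle_weights(g, rng_seed=seed)
        assert set(report.graph.edges()) == set(g.edges())
        assert report.graph.weight_multiset() == g.weight_multiset()
        assert report.succeeded == report.target

    def test_all_equal_weights_warns(self):
        g = WeightedGraph([("A", "B", 2), ("B", "C", 2), ("C", "D", 2)])
        report = shuffle_weights(g, rng_seed=0)
        assert report.succeeded == 0
        assert any("all weights equal" in w for w in report.warnings)

    def test_converges_to_uniform_permutation(self):
        """Position of the max weight is uniform over edges (chi-square)."""
        g = WeightedGraph(
            [("A", "B", 1), ("B", "C", 2), ("C", "D", 3), ("D", "E", 4), ("E", "F", 5), ("F", "A", 9)]
        )
        edges = g.edge_list()
        counts = dict.fromkeys(edges, 0)
        runs = 600
        for s in range(runs):
            out = shuffle_weights(g, n_swaps=50 * g.n_edges, rng_seed=s).graph
            top = max(edges, key=lambda e: out.weight(*e))
            counts[top] += 1
        chi2, p = stats.chisquare(list(counts.values()))
        assert p > 1e-3

    def test_determinism(self):
        g = make_graph(2)
        assert shuffle_weights(g, rng_seed=5).graph == shuffle_weights(g, rng_seed=5).graph


class TestRichClubMeasures:
    def test_complete_graph_coefficient_is_one(self):
        nodes = list("ABCDE")
        g = WeightedGraph(
            [(a, b, 1 + i) for i, (a, b) in enumerate(
                (a, b) for i_, a in enumerate(nodes) for b in nodes[i_ + 1:]
            )]
        )
        assert rich_club_coefficient(g, 0.5) == 1.0

    def test_disjoint_heavy_edges_score_zero(self):
        g = WeightedGraph([("A", "P", 5), ("B", "Q", 5)])
        # all strengths tie at 5; label order makes {A, B} the rich pair
        assert rich_club_coefficient(g, 0.5) == 0.0

    def test_toy_g0_rich_pair_connected(self, g0):
        # strengths: A=4, D=4, B=3, C=3 -> rich pair {A, D}, edge A-D exists
        spec = rich_club_spec(g0, 0.5)
        assert spec.rich_nodes == {"A", "D"}
        assert spec.coefficient == 1.0

    def test_rich_set_too_small(self):
        g = WeightedGraph([("A", "B", 1), ("B", "C", 1)])
        with pytest.raises(ValueError, match="at least 2"):
            rich_club_coefficient(g, 0.1)


class TestRewireRichClub:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_enhance_monotone_and_conserving(self, seed):
        g = make_graph(seed, n=100)
        report = rewire_rich_club(g, 0.05, "enhance", rng_seed=seed)
        assert_conserved(g, report.graph)
        assert report.extras["coefficient_after"] >= report.extras["coefficient_before"]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_destroy_monotone(self, seed):
        g = make_graph(seed, n=100)
        report = rewire_rich_club(g, 0.05, "destroy", rng_seed=seed)
        assert_conserved(g, report.graph)
        assert report.extras["coefficient_after"] <= report.extras["coefficient_before"]

    def test_stepwise_monotone_trajectory(self):
        g = make_graph(3, n=80)
        coeffs = [
            rewire_rich_club(g, 0.1, "enhance", max_iters=k, rng_seed=11).extras[
                "coefficient_after"
            ]
            for k in range(5)
        ]
        assert coeffs == sorted(coeffs)

    def test_complete_graph_saturated(self):
        nodes = list("ABCDEF")
        g = WeightedGraph(
            [(a, b, 1) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
        )
        report = rewire_rich_club(g, 0.5, "enhance", rng_seed=0)
        assert report.succeeded == 0 and report.target == 0

    def test_tiny_rich_set_rejected(self):
        g = WeightedGraph([("A", "B", 1), ("B", "C", 1)])
        with pytest.raises(ValueError, match="at least 2"):
            rewire_rich_club(g, 0.1, "enhance", rng_seed=0)

    def test_determinism(self):
        g = make_graph(1, n=80)
        a = rewire_rich_club(g, 0.05, "enhance", rng_seed=4)
        b = rewire_rich_club(g, 0.05, "enhance", rng_seed=4)
        assert a.graph == b.graph


class TestStrengthAssortativity:
    def test_two_matched_dyads_fully_assortative(self):
        g = WeightedGraph([("a", "b", 5), ("c", "d", 1)])
        assert strength_assortativity(g) == pytest.approx(1.0)

    def test_path_is_disassortative(self):
        g = WeightedGraph([("a", "b", 1), ("b", "c", 1)])
        assert strength_assortativity(g) == pytest.approx(-1.0)

    def test_zero_variance_raises(self):
        cyc = WeightedGraph([("A", "B", 1), ("B", "C", 1), ("C", "A", 1)])
        with pytest.raises(ValueError, match="zero variance"):
            strength_assortativity(cyc)


class TestRewireAssortativity:
    @pytest.mark.parametrize("direction,sign", [("assortative", 1), ("disassortative", -1)])
    def test_moves_mixing_in_commanded_direction(self, direction, sign):
        g = make_graph(0, n=100)
        report = rewire_assortativity(g, direction, rng_seed=2)
        assert_conserved(g, report.graph)
        delta = report.extras["assortativity_after"] - report.extras["assortativity_before"]
        assert sign * delta > 0

    def test_star_graph_has_no_valid_move(self):
        g = WeightedGraph([("hub", leaf, w) for w, leaf in enumerate("abcde", start=1)])
        report = rewire_assortativity(g, "assortative", n_swaps=5, rng_seed=0)
        assert report.succeeded == 0
        assert report.graph == g

    def test_determinism(self):
        g = make_graph(2)
        a = rewire_assortativity(g, "disassortative", rng_seed=8)
        b = rewire_assortativity(g, "disassortative", rng_seed=8)
        assert a.graph == b.graph


@pytest.fixture(scope="module")
def cases():
    return {c.name: c for c in fig_micro_cases()}


class TestFigureMicroCases:
    """Single-step semantics of each elementary move on the drawn 4-node cases."""

    def run_case(self, case, seed):
        ops = {
            "one_k": lambda g: rewire_1k(g, n_swaps=1, rng_seed=seed),
            "structure": lambda g: shuffle_structure(g, n_swaps=1, rng_seed=seed),
            "weight": lambda g: shuffle_weights(g, n_swaps=1, rng_seed=seed),
            "rich_club_enhance": lambda g: rewire_rich_club(
                g, case.params["rich_fraction"], "enhance", max_iters=1, rng_seed=seed
            ),
            "assortative": lambda g: rewire_assortativity(
                g, "assortative", n_swaps=1, rng_seed=seed
            ),
            "disassortative": lambda g: rewire_assortativity(
                g, "disassortative", n_swaps=1, rng_seed=seed
            ),
        }
        return ops[case.name](case.before)

    @pytest.mark.parametrize(
        "name",
        ["one_k", "structure", "weight", "rich_club_enhance", "assortative", "disassortative"],
    )
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_one_step_yields_drawn_outcome(self, cases, name, seed):
        case = cases[name]
        report = self.run_case(case, seed)
        assert report.succeeded == 1
        assert any(report.graph == out for out in case.outcomes())

    def test_weight_shuffle_worked_weights(self, cases):
        """The two selected weights trade places: AB:3, CD:2 -> AB:2, CD:3."""
        out = self.run_case(cases["weight"], 0).graph
        assert out.weight("A", "B") == 2 and out.weight("C", "D") == 3

    def test_rich_club_case_is_deterministic(self, cases):
        case = cases["rich_club_enhance"]
        for seed in range(4):
            assert self.run_case(case, seed).graph == case.after
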