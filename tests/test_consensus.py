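"""Modularity, greedy detection vs exact oracle, refinement provenance."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from themesort import (
    CreateTheme,
    MoveQuote,
    QuoteCorpus,
    RaterSort,
    RenameTheme,
    RetainTheme,
    SortStudy,
    apply_refinement,
    build_network,
    detect_communities,
    exact_max_modularity,
    modularity,
    theme_set_from_partition,
)
from themesort.errors import ConfigError, CoverageError, ReferenceError_, SizeError
from themesort.network import from_weights

from conftest import random_study


def random_network(rng, n_nodes, max_weight=4):
    weights = {}
    for i in range(1, n_nodes + 1):
        for j in range(i + 1, n_nodes + 1):
            weights[(i, j)] = int(rng.integers(0, max_weight + 1))
    return from_weights(weights, nodes=range(1, n_nodes + 1))


class TestModularity:
    def test_all_in_one_is_zero(self, two_triangles):
        assert modularity({i: 1 for i in range(1, 7)}, two_triangles) == pytest.approx(0.0)

    def test_two_triangle_partition_is_half(self, two_triangles):
        part = {1: 1, 2: 1, 3: 1, 4: 2, 5: 2, 6: 2}
        assert modularity(part, two_triangles) == pytest.approx(0.5)

    def test_all_singletons_is_minus_one_sixth(self, two_triangles):
        part = {i: i for i in range(1, 7)}
        assert modularity(part, two_triangles) == pytest.approx(-1 / 6)

    def test_zero_edges_convention(self):
        net = from_weights({}, nodes=[1, 2, 3])
        assert modularity({1: 1, 2: 1, 3: 2}, net) == 0.0

    def test_matches_networkx_on_random_networks(self, rng):
        """Independent cross-check of the weighted-modularity formula."""
        for _ in range(15):
            net = random_network(rng, int(rng.integers(4, 10)))
            if net.total_weight == 0:
                continue
            part = {i: int(rng.integers(1, 4)) for i in net.node_ids}
            comms = {}
            for q, c in part.items():
                comms.setdefault(c, set()).add(q)
            gamma = float(rng.uniform(0.5, 2.0))
            expected = nx.community.modularity(
                net.graph, comms.values(), weight="weight", resolution=gamma
            )
            assert modularity(part, net, gamma) == pytest.approx(expected)

    def test_missing_node_raises_coverage_error(self, two_triangles):
        with pytest.raises(CoverageError, match="6"):
            modularity({i: 1 for i in range(1, 6)}, two_triangles)

    def test_merge_delta_matches_analytic_formula(self, rng):
        """Merging communities a and b changes Q by w_ab/m - 2*gamma*S_a*S_b/(2m)^2."""
        for _ in range(10):
            net = random_network(rng, 8)
            m = net.total_weight
            if m == 0:
                continue
            part = {i: 1 if i <= 4 else 2 for i in net.node_ids}
            q_before = modularity(part, net)
            merged = {i: 1 for i in net.node_ids}
            q_after = modularity(merged, net)
            w_ab = sum(
                net.weight(i, j) for i in range(1, 5) for j in range(5, 9)
            )
            s_a = sum(net.strength(i) for i in range(1, 5))
            s_b = sum(net.strength(i) for i in range(5, 9))
            delta = w_ab / m - 2 * s_a * s_b / (2 * m) ** 2
            assert q_after - q_before == pytest.approx(delta)


class TestDetectCommunities:
    def test_recovers_planted_groups_from_identical_sorts(self):
        base = {q: f"g{(q - 1) % 5}" for q in range(1, 41)}
        sorts = [RaterSort(f"r{k}", dict(base)) for k in range(8)]
        study = SortStudy(QuoteCorpus.from_ids(range(1, 41)), sorts)
        part = detect_communities(build_network(study), seed=0)
        assert part.n_communities == 5
        groups = part.communities()
        expected = {}
        for q, g in base.items():
            expected.setdefault(g, set()).add(q)
        assert set(map(frozenset, groups.values())) == set(map(frozenset, expected.values()))

    @pytest.mark.parametrize("n_raters", [1, 2, 5])
    def test_identical_sorts_recovered_for_any_rater_count(self, n_raters):
        base = {1: "a", 2: "a", 3: "a", 4: "b", 5: "b", 6: "c", 7: "c", 8: "c"}
        sorts = [RaterSort(f"r{k}", dict(base)) for k in range(n_raters)]
        study = SortStudy(QuoteCorpus.from_ids(range(1, 9)), sorts)
        part = detect_communities(build_network(study), seed=3)
        assert set(map(frozenset, part.communities().values())) == {
            frozenset({1, 2, 3}),
            frozenset({4, 5}),
            frozenset({6, 7, 8}),
        }

    def test_zero_weight_network_gives_singletons(self):
        net = from_weights({}, nodes=[1, 2, 3, 4])
        part = detect_communities(net, seed=0)
        assert part.n_communities == 4
        assert part.modularity_value == 0.0

    def test_isolated_node_ends_as_singleton(self):
        net = from_weights({(1, 2): 3}, nodes=[1, 2, 3])
        part = detect_communities(net, seed=0)
        assert part.assignment[3] not in (part.assignment[1],)
        assert part.communities()[part.assignment[3]] == {3}

    def test_deterministic_given_seed(self, rng):
        net = random_network(rng, 12)
        a = detect_communities(net, seed=42)
        b = detect_communities(net, seed=42)
        assert a.assignment == b.assignment
        assert a.modularity_value == b.modularity_value

    def test_community_ids_ordered_by_size_then_smallest_member(self):
        net = from_weights({(1, 2): 5, (3, 4): 5, (4, 5): 5, (3, 5): 5})
        part = detect_communities(net, seed=0)
        # the size-3 community {3,4,5} gets id 1, the pair {1,2} id 2
        assert part.assignment[3] == 1
        assert part.assignment[1] == 2

    def test_invalid_resolution_rejected(self, two_triangles):
        with pytest.raises(ConfigError):
            detect_communities(two_triangles, resolution=0.0)

    def test_reported_q_matches_recomputation(self, rng):
        net = random_network(rng, 10)
        part = detect_communities(net, seed=7)
        assert part.modularity_value == pytest.approx(
            modularity(part.assignment, net, part.resolution)
        )


class TestExactOracle:
    def test_two_triangles_optimum(self, two_triangles):
        part = exact_max_modularity(two_triangles)
        assert part.modularity_value == pytest.approx(0.5)
        assert set(map(frozenset, part.communities().values())) == {
            frozenset({1, 2, 3}),
            frozenset({4, 5, 6}),
        }

    def test_single_node(self):
        net = from_weights({}, nodes=[1])
        part = exact_max_modularity(net)
        assert part.assignment == {1: 1}
        assert part.modularity_value == 0.0

    def test_complete_equal_weight_graph_is_one_community(self):
        weights = {(i, j): 2 for i in range(1, 6) for j in range(i + 1, 6)}
        part = exact_max_modularity(from_weights(weights))
        assert part.n_communities == 1

    def test_size_limit(self):
        net = from_weights({(i, i + 1): 1 for i in range(1, 13)})  # 13 nodes
        with pytest.raises(SizeError):
            exact_max_modularity(net)

    def test_greedy_never_beats_exact(self, rng):
        for trial in range(20):
            net = random_network(rng, int(rng.integers(4, 9)))
            greedy = detect_communities(net, seed=trial)
            exact = exact_max_modularity(net)
            assert greedy.modularity_value <= exact.modularity_value + 1e-9


class TestRefinement:
    def make_partition(self):
        base = {q: "a" if q <= 5 else "b" for q in range(1, 11)}
        sorts = [RaterSort(f"r{k}", dict(base)) for k in range(3)]
        study = SortStudy(QuoteCorpus.from_ids(range(1, 11)), sorts)
        net = build_network(study)
        return detect_communities(net, seed=0), net

    def test_no_actions_gives_default_labels(self):
        part, _ = self.make_partition()
        ts = apply_refinement(part, [])
        assert set(ts.themes) == {"Group 1", "Group 2"}
        assert ts.provenance == []

    def test_create_theme_and_move_quotes(self):
        """Create an extra theme and move six quotes into it, as when
        co-researchers split a detected grouping into a new theme."""
        part, net = self.make_partition()
        actions = [CreateTheme("Future Courses", rationale="agreed in session")]
        actions += [MoveQuote(q, "Future Courses") for q in (1, 2, 3, 6, 7, 8)]
        ts = apply_refinement(part, actions, net=net)
        assert ts.n_themes == 3
        assert ts.themes["Future Courses"] == {1, 2, 3, 6, 7, 8}
        assert len(ts.provenance) == 7
        assert sorted(ts.covered()) == list(range(1, 11))

    def test_refined_modularity_matches_recomputation(self):
        part, net = self.make_partition()
        ts = apply_refinement(
            part, [CreateTheme("solo"), MoveQuote(1, "solo")], net=net
        )
        labels = {lab: i + 1 for i, lab in enumerate(ts.themes)}
        assignment = {q: labels[lab] for q, lab in ts.assignment.items()}
        assert ts.modularity_value == pytest.approx(modularity(assignment, net))
        # human-led edits may lower Q relative to the detected optimum
        assert ts.modularity_value <= part.modularity_value

    def test_move_unknown_quote_rejected(self):
        part, _ = self.make_partition()
        with pytest.raises(ReferenceError_, match="99"):
            apply_refinement(part, [MoveQuote(99, "Group 1")])

    def test_move_to_uncreated_theme_rejected(self):
        part, _ = self.make_partition()
        with pytest.raises(ReferenceError_, match="create"):
            apply_refinement(part, [MoveQuote(1, "Brand New")])

    def test_emptied_theme_dropped_unless_retained(self):
        part, _ = self.make_partition()
        moves = [MoveQuote(q, "Group 1") for q in range(6, 11)]
        ts = apply_refinement(part, moves)
        assert set(ts.themes) == {"Group 1"}
        ts2 = apply_refinement(part, [RetainTheme("Group 2")] + moves)
        assert ts2.themes["Group 2"] == set()

    def test_rename_preserves_members(self):
        part, _ = self.make_partition()
        ts = apply_refinement(part, [RenameTheme("Group 1", "Participatory Approach")])
        assert "Participatory Approach" in ts.themes
        assert "Group 1" not in ts.themes
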