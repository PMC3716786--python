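import itertools

import networkx as nx
import numpy as np
import pytest

from linehap import genotypes as gt
from linehap import ilp
from linehap import linegraph as lg
from tests.conftest import random_graph, matrix_from_pool


def brute_min_edge_deletions(g: nx.Graph) -> int:
    """Exhaustive oracle: smallest edge subset whose removal leaves a line graph."""
    edges = list(g.edges())
    for r in range(len(edges) + 1):
        for subset in itertools.combinations(edges, r):
            h = g.copy()
            h.remove_edges_from(subset)
            if lg.is_line_graph(h):
                return r
    raise AssertionError("unreachable: empty graph is a line graph")


def brute_min_node_deletions(g: nx.Graph) -> int:
    """Exhaustive oracle: smallest node subset whose removal leaves a line graph."""
    nodes = list(g.nodes())
    for r in range(len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            h = g.subgraph([v for v in nodes if v not in subset])
            if lg.is_line_graph(h):
                return r
    raise AssertionError("unreachable")


def check_solution(g: nx.Graph, sol: ilp.DeletionSolution) -> None:
    """Every solution must leave an allelable line graph behind."""
    h = g.copy()
    h.remove_nodes_from(sol.deleted_nodes)
    h.remove_edges_from(sol.deleted_edges)
    h.add_edges_from(sol.inserted_edges)
    assert lg.is_line_graph(h)
    assert lg.verify_allelable(h, sol.assignment)
    assert sol.estimated_haplotypes == lg.count_haplotypes(sol.assignment)


class TestEdgeDeletion:
    def test_claw_needs_one_deletion(self, claw):
        sol = ilp.solve_edge_deletion(claw)
        assert sol.objective == 1
        assert len(sol.deleted_edges) == 1
        check_solution(claw, sol)

    def test_line_graph_needs_none(self):
        g = nx.line_graph(nx.petersen_graph())
        sol = ilp.solve_edge_deletion(g)
        assert sol.objective == 0
        assert not sol.deleted_edges

    def test_empty_graph_uses_two_colors_per_node(self):
        sol = ilp.solve_edge_deletion(nx.empty_graph(5))
        assert sol.objective == 0
        assert sol.estimated_haplotypes == 10

    def test_matches_bruteforce_on_small_graphs(self, rng):
        """ILP optimum equals exhaustive minimum on graphs with <= 6 nodes."""
        for _ in range(60):
            g = random_graph(rng, 2, 6)
            sol = ilp.solve_edge_deletion(g, shortcut=False)
            assert sol.status == "optimal"
            assert sol.objective == brute_min_edge_deletions(g)
            check_solution(g, sol)

    def test_shortcut_agrees_with_ilp(self, rng):
        for _ in range(20):
            g = random_graph(rng, 2, 7)
            a = ilp.solve_edge_deletion(g, shortcut=True)
            b = ilp.solve_edge_deletion(g, shortcut=False)
            assert a.objective == b.objective

    def test_monotonicity_under_edge_addition(self, rng):
        """Adding k edges can raise the optimum by at most k."""
        for _ in range(10):
            g = random_graph(rng, 4, 6)
            base = ilp.solve_edge_deletion(g).objective
            non_edges = [e for e in itertools.combinations(g.nodes(), 2) if not g.has_edge(*e)]
            if not non_edges:
                continue
            k = min(2, len(non_edges))
            g2 = g.copy()
            g2.add_edges_from(non_edges[:k])
            after = ilp.solve_edge_deletion(g2).objective
            assert after <= base + k


class TestSymmetryAndPruning:
    def test_basic_constraint_families_present(self, claw):
        model = ilp.build_edge_deletion_ilp(claw)
        n = claw.number_of_nodes()
        # two colors per node (eq), nonadjacency bans, sharing consistency
        eqs = [c for c in model.constraints if c[1] == c[2] == 2]
        assert len(eqs) == n
        assert any(c[1] == c[2] == 1 for c in model.constraints)  # sum s + d = 1

    def test_owner_first_use_convention(self, rng):
        """A color owned by node i is used by a later node only if i uses it."""
        g = random_graph(rng, 4, 6, p=0.5)
        model = ilp.prune_variables(ilp.add_symmetry_breaking(ilp.build_edge_deletion_ilp(g)), g)
        res = ilp.solve_model(model)
        order, index = model.meta["order"], model.meta["index"]
        for v in order:
            for u in order:
                if index[u] <= index[v]:
                    continue
                for j in (2 * index[v] - 1, 2 * index[v]):
                    uses = res.values.get(("x", u, j), 0)
                    owner_uses = res.values.get(("x", v, j), 0)
                    assert uses <= owner_uses

    def test_symmetry_and_pruning_preserve_optimum(self, rng):
        """Paired solves: plain vs +symmetry vs +pruning all agree."""
        for _ in range(20):
            g = random_graph(rng, 2, 6)
            base = ilp.build_edge_deletion_ilp(g)
            sym = ilp.add_symmetry_breaking(base)
            pruned = ilp.prune_variables(sym, g)
            objs = [ilp.solve_model(m).objective for m in (base, sym, pruned)]
            assert objs[0] == objs[1] == objs[2]
            assert pruned.n_vars <= sym.n_vars

    def test_pruning_requires_symmetry(self, claw):
        with pytest.raises(ValueError):
            ilp.prune_variables(ilp.build_edge_deletion_ilp(claw), claw)


class TestNodeDeletion:
    def test_claw_and_star(self, claw):
        assert ilp.solve_node_deletion(claw).objective == 1
        sol = ilp.solve_node_deletion(nx.star_graph(4))
        assert sol.objective == 1
        assert sol.deleted_nodes == {0}  # the hub hits all four claws

    def test_line_graph_deletes_nothing(self):
        sol = ilp.solve_node_deletion(nx.complete_graph(4))
        assert sol.objective == 0

    def test_matches_bruteforce_on_small_graphs(self, rng):
        for _ in range(40):
            g = random_graph(rng, 2, 6)
            sol = ilp.solve_node_deletion(g)
            assert sol.objective == brute_min_node_deletions(g)
            check_solution(g, sol)


class TestCombined:
    def test_large_alpha_reduces_to_edge_deletion(self, rng):
        for _ in range(10):
            g = random_graph(rng, 3, 6)
            alpha = g.number_of_edges() + 1
            combined = ilp.solve_combined(g, alpha, shortcut=False)
            edge_only = ilp.solve_edge_deletion(g, shortcut=False)
            assert combined.objective == edge_only.objective
            assert not combined.deleted_nodes

    def test_hub_of_claws_removed_at_low_alpha(self):
        # one node whose removal kills two separate claws: two edge
        # deletions otherwise, one node deletion at cost 1.5 preferred
        g = nx.Graph()
        g.add_edges_from([("c", x) for x in "abdefg"])
        # leaves arranged so c centres two disjoint claws {a,b,d}, {e,f,g}
        sol = ilp.solve_combined(g, alpha=1.5)
        assert sol.deleted_nodes == {"c"}
        check_solution(g, sol)

    def test_objective_bounded_by_pure_strategies(self, rng):
        for _ in range(10):
            g = random_graph(rng, 3, 6)
            alpha = 1.5
            combined = ilp.solve_combined(g, alpha, shortcut=False).objective
            edge_only = ilp.solve_edge_deletion(g, shortcut=False).objective
            node_only = ilp.solve_node_deletion(g).objective
            assert combined <= edge_only + 1e-9
            assert combined <= alpha * node_only + 1e-9

    def test_solution_feasible(self, rng):
        for _ in range(10):
            g = random_graph(rng, 3, 6)
            sol = ilp.solve_combined(g, 1.5, shortcut=False)
            check_solution(g, sol)


class TestEdit:
    def test_claw_one_edit(self, claw):
        sol = ilp.solve_edit(claw)
        assert sol.objective == 1
        assert len(sol.deleted_edges) + len(sol.inserted_edges) == 1
        check_solution(claw, sol)

    def test_line_graph_no_edits(self):
        sol = ilp.solve_edit(nx.complete_graph(3))
        assert sol.objective == 0
        assert not sol.deleted_edges and not sol.inserted_edges

    def test_editing_never_worse_than_deletion_only(self, rng):
        for _ in range(8):
            g = random_graph(rng, 3, 5)
            edit = ilp.solve_edit(g)
            delete = ilp.solve_edge_deletion(g, shortcut=False)
            assert edit.objective <= delete.objective + 1e-9
            check_solution(g, edit)

    def test_weights_steer_the_choice(self, claw):
        # make deleting any existing edge expensive; inserting leaf pairs cheap
        weights = {frozenset(e): 10.0 for e in claw.edges()}
        for u, v in itertools.combinations([1, 2, 3], 2):
            weights[frozenset((u, v))] = 1.0
        sol = ilp.solve_edit(claw, weights=weights)
        assert not sol.deleted_edges
        assert sol.inserted_edges  # cheaper to complete the claw into a paw/diamond
        check_solution(claw, sol)


class TestParsimony:
    def test_isolated_node_and_single_edge(self):
        g1 = nx.empty_graph(1)
        assert ilp.solve_min_haplotypes(g1)[0] == 2
        g2 = nx.path_graph(2)
        count, a, I, _ = ilp.solve_min_haplotypes(g2)
        assert count == 3
        assert set(I) == {(0, 1)}  # I maps each sharing edge to its color

    def test_lower_bound_vs_edge_deletion(self, rng):
        """Relaxing edges to optional can only reduce the color count."""
        for _ in range(12):
            g = random_graph(rng, 2, 6)
            count, _, _, _ = ilp.solve_min_haplotypes(g)
            sol = ilp.solve_edge_deletion(g, shortcut=False)
            assert count <= sol.estimated_haplotypes
            assert count <= 2 * g.number_of_nodes()

    def test_objective_counts_used_colors(self, rng):
        g = random_graph(rng, 3, 6, p=0.4)
        count, a, I, res = ilp.solve_min_haplotypes(g)
        assert count == lg.count_haplotypes(a)
        assert res.objective == count


class TestPipeline:
    def test_line_graph_input_removes_nothing(self, toy_matrix):
        m, _ = toy_matrix
        report = ilp.estimate_population_size(m, "edge")
        assert report["edges_removed"] == 0
        assert report["estimated_haplotypes"] == 4

    def test_modes_report_consistent_fields(self, toy_matrix):
        m, _ = toy_matrix
        for mode in ("edge", "node", "combined", "edit", "parsimony"):
            report = ilp.estimate_population_size(m, mode)
            assert report["status"] == "optimal"
            assert report["estimated_haplotypes"] >= 2

    def test_unknown_mode_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            ilp.estimate_population_size(toy_matrix[0], "magic")

    def test_duplicates_noted_not_counted(self):
        pool = np.array([[0, 1, 0, 1], [1, 0, 1, 0], [1, 1, 0, 0]])
        m = matrix_from_pool(pool, [(0, 1), (0, 1), (1, 2)])
        report = ilp.estimate_population_size(m, "edge")
        assert report["collapsed_duplicates"] == {"g0": ["g0", "g1"]}
        assert report["n_genotypes"] == 2
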