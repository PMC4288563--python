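"""Matrix-tree steady states: enumeration, kernel bases, conservation."""

import itertools

import numpy as np
import pytest

from linframe import (
    build_graph,
    count_rooted_spanning_trees,
    enumerate_rooted_spanning_trees,
    is_strongly_connected,
    kernel_basis,
    rho_matrix_tree,
    steady_state_from_initial,
    steady_state_probabilities,
)
from linframe.dynamics import integrate_master_equation
from linframe.fixtures import random_strongly_connected
from linframe.graph import laplacian
from linframe.models import build_stabilized_array
from linframe.poly import LabelPolynomial, poly_eval


def brute_force_trees(g, root):
    """Oracle: test every (n-1)-subset of edges for the in-tree property."""
    n = g.n
    found = set()
    for subset in itertools.combinations(g.edges, n - 1):
        outdeg = {}
        ok = True
        for (i, j) in subset:
            if i in outdeg:
                ok = False
                break
            outdeg[i] = j
        if not ok or root in outdeg:
            continue
        if set(outdeg) != set(range(1, n + 1)) - {root}:
            continue
        # every vertex must reach the root
        for v in outdeg:
            seen = set()
            w = v
            while w != root:
                if w in seen or w not in outdeg:
                    ok = False
                    break
                seen.add(w)
                w = outdeg[w]
            if not ok:
                break
        if ok:
            found.add(frozenset(subset))
    return found


class TestEnumeration:
    def test_three_cycle_single_tree(self, three_cycle):
        trees = enumerate_rooted_spanning_trees(three_cycle, 1)
        assert len(trees) == 1
        assert trees[0].edges == frozenset({(2, 3), (3, 1)})

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_subset_oracle(self, seed):
        g = random_strongly_connected(5, 0.35, seed=seed)
        for root in (1, 3):
            enumerated = {t.edges for t in enumerate_rooted_spanning_trees(g, root)}
            assert enumerated == brute_force_trees(g, root)

    @pytest.mark.parametrize("n,count", [(4, 16), (5, 125)])
    def test_cayley_counts_on_complete_bidirected_graph(self, n, count):
        edges = [
            (i, j, 1.0) for i in range(1, n + 1) for j in range(1, n + 1) if i != j
        ]
        g = build_graph(n, edges)
        assert count_rooted_spanning_trees(g, 1) == count
        assert len(enumerate_rooted_spanning_trees(g, 2)) == count

    def test_no_tree_when_root_unreachable(self, chain):
        assert enumerate_rooted_spanning_trees(chain, 1) == []

    def test_invalid_root(self, chain):
        with pytest.raises(ValueError):
            enumerate_rooted_spanning_trees(chain, 9)


class TestRhoMatrixTree:
    def test_two_state(self, two_state):
        rho = rho_matrix_tree(two_state)
        assert rho == [LabelPolynomial.symbol("b"), LabelPolynomial.symbol("a")]

    def test_three_cycle(self, three_cycle):
        b, c, a = (LabelPolynomial.symbol(s) for s in "bca")
        assert rho_matrix_tree(three_cycle) == [b * c, c * a, a * b]

    def test_requires_strong_connectivity(self, chain):
        with pytest.raises(ValueError, match="kernel_basis"):
            rho_matrix_tree(chain)

    @pytest.mark.parametrize("seed", range(4))
    def test_numeric_routes_agree(self, seed):
        """Symbolic tree sums, principal minors and the numeric null
        space must all give the same direction."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        g = random_strongly_connected(n, 0.4, seed=seed, labels="symbolic")
        env = {s: float(rng.uniform(0.1, 5.0)) for s in g.symbols}
        sym = np.array([float(poly_eval(p, env)) for p in rho_matrix_tree(g)])
        num = rho_matrix_tree(g, mode="numeric", env=env)
        assert np.allclose(sym, num, rtol=1e-9)
        L = laplacian(g, env)
        _, _, vt = np.linalg.svd(L)
        null = vt[-1]
        null = null * np.sign(null[np.argmax(np.abs(null))])
        assert np.allclose(num / num.sum(), null / null.sum(), rtol=1e-8)
        # tree count equals the deleted-row/column determinant oracle
        assert count_rooted_spanning_trees(g, 1) == len(
            enumerate_rooted_spanning_trees(g, 1)
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_entries_homogeneous_of_degree_n_minus_1(self, seed):
        g = random_strongly_connected(5, 0.3, seed=seed, labels="symbolic")
        for p in rho_matrix_tree(g):
            assert p.total_degrees() == {g.n - 1}

    @pytest.mark.parametrize("seed", range(3))
    def test_strong_connectivity_iff_trees_at_every_root(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 5
        edges = {
            (int(i), int(j))
            for i, j in rng.integers(1, n + 1, (12, 2))
            if i != j
        }
        # keep weakly connected: chain through all vertices
        edges |= {(k, k + 1) for k in range(1, n)}
        g = build_graph(n, [(i, j, 1.0) for i, j in edges])
        has_tree_everywhere = all(
            len(enumerate_rooted_spanning_trees(g, r)) > 0 for r in range(1, n + 1)
        )
        assert has_tree_everywhere == is_strongly_connected(g)


class TestSteadyStateProbabilities:
    def test_two_state_normalisation(self, two_state):
        u = steady_state_probabilities(two_state, {"a": 2, "b": 6}).probabilities
        assert u == pytest.approx([0.75, 0.25])

    def test_all_positive_and_sum_one(self):
        g = random_strongly_connected(7, 0.35, seed=5)
        env = {}
        u = steady_state_probabilities(g, env).probabilities
        assert (u > 0).all()
        assert abs(u.sum() - 1.0) < 1e-12

    def test_scale_invariance(self):
        g = random_strongly_connected(5, 0.4, seed=9, labels="symbolic")
        env = {s: float(v) for s, v in zip(sorted(g.symbols), range(1, 99))}
        lam = 37.0
        scaled = {s: lam * v for s, v in env.items()}
        u1 = steady_state_probabilities(g, env).probabilities
        u2 = steady_state_probabilities(g, scaled).probabilities
        assert np.allclose(u1, u2, rtol=1e-9)


class TestKernelBasis:
    def test_strongly_connected_reduces_to_matrix_tree(self, three_cycle):
        basis = kernel_basis(three_cycle, mode="symbolic")
        assert len(basis) == 1
        assert basis[0] == rho_matrix_tree(three_cycle)

    def test_chain_absorbs_at_terminal_vertex(self, chain):
        basis = kernel_basis(chain, mode="numeric", env={"a": 1, "b": 2})
        assert len(basis) == 1
        assert np.allclose(basis[0], [0, 0, 1])

    def test_stabilized_array_has_two_extreme_indicators(self):
        g = build_stabilized_array(2, nucleation_on=False)
        basis = kernel_basis(g, mode="numeric", env={"k_plus": 1, "k_minus": 1, "k_star": 1})
        assert len(basis) == 2
        unmarked = g.vertex_by_name("00").index
        stably_marked = g.vertex_by_name("22").index
        expected = {unmarked, stably_marked}
        supports = {int(np.argmax(b)) + 1 for b in basis}
        assert supports == expected
        for b in basis:
            assert b.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_kernel_dimension_equals_terminal_scc_count(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = 6
        edges = {(k, k + 1) for k in range(1, n)}
        edges |= {
            (int(i), int(j)) for i, j in rng.integers(1, n + 1, (8, 2)) if i != j
        }
        g = build_graph(n, [(i, j, float(rng.uniform(0.5, 2))) for i, j in edges])
        env = {}
        basis = kernel_basis(g, mode="numeric", env=env)
        L = laplacian(g, env)
        rank = np.linalg.matrix_rank(L, tol=1e-10)
        assert len(basis) == g.n - rank
        for b in basis:
            assert np.abs(L @ b).max() < 1e-9 * max(np.abs(b).max(), 1)


class TestSteadyStateFromInitial:
    def test_memory_loss_when_strongly_connected(self, three_cycle):
        env = {"a": 1.0, "b": 2.0, "c": 0.7}
        direct = steady_state_probabilities(three_cycle, env).probabilities
        for x0 in ([1, 0, 0], [0.2, 0.5, 0.3]):
            ss = steady_state_from_initial(three_cycle, env, x0)
            assert np.allclose(ss.probabilities, direct, rtol=1e-9)

    def test_chain_collapses_to_absorbing_state(self, chain):
        env = {"a": 1.0, "b": 0.5}
        ss = steady_state_from_initial(chain, env, [1, 0, 0])
        assert np.allclose(ss.state, [0, 0, 1], atol=1e-12)
        # ODE oracle
        u = integrate_master_equation(chain, env, [1, 0, 0], [200.0])[-1]
        assert np.allclose(ss.state, u, atol=1e-6)

    def test_mass_on_one_terminal_scc_stays_there(self):
        g = build_stabilized_array(2, nucleation_on=False)
        env = {"k_plus": 1.0, "k_minus": 1.0, "k_star": 0.5}
        x0 = np.zeros(g.n)
        x0[g.vertex_by_name("22").index - 1] = 1.0
        ss = steady_state_from_initial(g, env, x0)
        assert ss.state[g.vertex_by_name("22").index - 1] == pytest.approx(1.0)
        assert np.abs(np.delete(ss.state, g.vertex_by_name("22").index - 1)).max() < 1e-10

    def test_mass_conserved(self):
        g = build_stabilized_array(1, nucleation_on=False)
        env = {"k_plus": 1.0, "k_minus": 1.0, "k_star": 0.5}
        ss = steady_state_from_initial(g, env, [0.3, 0.9, 0.6])
        assert ss.state.sum() == pytest.approx(1.8)

    def test_negative_initial_rejected(self, chain):
        with pytest.raises(ValueError):
            steady_state_from_initial(chain, {"a": 1, "b": 1}, [1, -1, 0])
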