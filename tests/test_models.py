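"""Model builders: nucleosome arrays, PHO5, titratable graphs."""

import itertools

import numpy as np
import pytest

from linframe import (
    build_equilibrium_array,
    build_graph,
    build_nucleosome_array,
    build_pho5_graph,
    build_stabilized_array,
    build_titratable_graph,
    count_rooted_spanning_trees,
    cycle_condition_holds,
    equilibrium_array_probability,
    hill_association,
    is_strongly_connected,
    pho5_transcribing_indicator,
    rapid_equilibrium_label,
    scc_decomposition,
    steady_state_probabilities,
)


def brute_force_array_edges(n):
    """All single-bit changes allowed by the nucleation/propagation/
    turnover rules, built straight from the rule text."""
    edges = set()
    for bits in itertools.product("01", repeat=n):
        s = "".join(bits)
        for k in range(n):
            if s[k] == "1":
                edges.add((s, s[:k] + "0" + s[k + 1:]))
            else:
                marked_neighbour = (k > 0 and s[k - 1] == "1") or (
                    k < n - 1 and s[k + 1] == "1"
                )
                if k == n - 1 or marked_neighbour:
                    edges.add((s, s[:k] + "1" + s[k + 1:]))
    return edges


class TestNucleosomeArray:
    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6])
    def test_vertex_count_and_connectivity(self, n):
        g = build_nucleosome_array(n)
        assert g.n == 2**n
        assert is_strongly_connected(g)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_edges_match_brute_force_rules(self, n):
        g = build_nucleosome_array(n)
        got = {(g.vertex(i).name, g.vertex(j).name) for (i, j) in g.edges}
        assert got == brute_force_array_edges(n)

    def test_labels_follow_bit_count(self):
        g = build_nucleosome_array(3)
        for (i, j), lab in g.edges.items():
            up = g.vertex(j).attributes["beta"] - g.vertex(i).attributes["beta"]
            assert str(lab) == ("k_plus" if up == 1 else "k_minus")

    def test_single_site_closed_form(self):
        g = build_nucleosome_array(1)
        K = 2.5
        u = steady_state_probabilities(g, {"k_plus": K, "k_minus": 1.0}).probabilities
        assert u[1] == pytest.approx(K / (1 + K))

    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_probabilities_depend_only_on_ratio(self, n):
        g = build_nucleosome_array(n)
        u1 = steady_state_probabilities(g, {"k_plus": 1.5, "k_minus": 1.0}).probabilities
        u2 = steady_state_probabilities(g, {"k_plus": 15.0, "k_minus": 10.0}).probabilities
        assert np.allclose(u1, u2, rtol=1e-9)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            build_nucleosome_array(0)
        with pytest.raises(ValueError):
            build_nucleosome_array(21)


class TestStabilizedArray:
    def test_five_sccs_two_terminal(self):
        g = build_stabilized_array(2, nucleation_on=False)
        assert g.n == 9
        dec = scc_decomposition(g)
        assert len(dec.components) == 5
        terminals = {
            next(iter(c)) for c, t in zip(dec.components, dec.terminal) if t
        }
        assert {g.vertex(v).name for v in terminals} == {"00", "22"}

    def test_nucleation_keeps_single_terminal_chain(self):
        g = build_stabilized_array(1, nucleation_on=True)
        assert g.n == 3
        dec = scc_decomposition(g)
        assert sum(dec.terminal) == 1
        from linframe import steady_state_from_initial

        ss = steady_state_from_initial(
            g, {"k_plus": 1.0, "k_minus": 0.5, "k_star": 0.7}, [1, 0, 0]
        )
        assert np.allclose(ss.state, [0, 0, 1], atol=1e-10)

    def test_vertex_count(self):
        assert build_stabilized_array(3).n == 27

    def test_propagation_from_stabilized_sites(self):
        """A stably marked neighbour can still seed new marks: state 02
        must not be terminal."""
        g = build_stabilized_array(2, nucleation_on=False)
        src = g.vertex_by_name("02").index
        assert any(i == src for (i, j) in g.edges)


class TestEquilibriumArray:
    def test_probabilities_sum_to_one(self):
        total = sum(
            equilibrium_array_probability(3, 1.7, format(k, "03b")) for k in range(8)
        )
        assert total == pytest.approx(1.0)

    def test_single_site(self):
        assert equilibrium_array_probability(1, 1.0, "1") == pytest.approx(0.5)

    @pytest.mark.parametrize("n", [2, 3])
    def test_matches_reversibilised_graph(self, n):
        g = build_equilibrium_array(n)
        K = 1.8
        ok, _ = cycle_condition_holds(g, {"k_plus": K, "k_minus": 1.0})
        assert ok
        u = steady_state_probabilities(g, {"k_plus": K, "k_minus": 1.0}).probabilities
        for v in g.vertices:
            assert u[v.index - 1] == pytest.approx(
                equilibrium_array_probability(n, K, v.name), rel=1e-9
            )

    def test_depends_only_on_mark_count(self):
        assert equilibrium_array_probability(4, 2.0, "0110") == pytest.approx(
            equilibrium_array_probability(4, 2.0, "1001")
        )


class TestPho5:
    def test_wild_type_structure(self, pho5_graph):
        assert pho5_graph.n == 12
        assert is_strongly_connected(pho5_graph)
        g = pho5_transcribing_indicator(pho5_graph)
        assert sum(g) == 6

    def test_transcribing_iff_nucleosome_minus_1_absent(self, pho5_graph):
        for v in pho5_graph.vertices:
            assert v.attributes["transcribing"] == (not v.attributes["nuc1"])

    def test_occlusion_constraint(self, pho5_graph):
        for v in pho5_graph.vertices:
            if v.attributes["uasp2"] == "pho4":
                assert v.attributes["uasp2"] != "nucleosome"

    def test_reference_microstate_is_fully_closed(self, pho5_graph):
        ref = pho5_graph.vertex(1).attributes
        assert not ref["pho4_uasp1"] and ref["uasp2"] == "nucleosome" and ref["nuc1"]

    def test_variant_moves_dissociation_labels_only(self):
        """Affinity codes move the b/c dissociation labels between the
        site positions; edge structure (and so the tree count) is
        unchanged."""
        lh, hl = build_pho5_graph("LH"), build_pho5_graph("HL")
        assert set(lh.edges) == set(hl.edges)
        for (i, j) in lh.edges:
            l_lh, l_hl = str(lh.edges[(i, j)]), str(hl.edges[(i, j)])
            if l_lh == "b":
                assert l_hl == "c"
            elif l_lh == "c":
                assert l_hl == "b"
            else:
                assert l_hl == l_lh
        assert count_rooted_spanning_trees(hl) == count_rooted_spanning_trees(lh)

    @pytest.mark.parametrize("code", ["LX", "HX"])
    def test_deleting_the_nucleosomal_site_leaves_8_connected_vertices(self, code):
        g = build_pho5_graph(code)
        assert g.n == 8
        assert is_strongly_connected(g)

    @pytest.mark.parametrize("code", ["XH", "XL"])
    def test_deleting_the_exposed_site_closes_the_promoter(self, code):
        """Without UASp1 there is no trigger for nucleosome -2 removal:
        6 vertices, not strongly connected, and the only terminal SCC
        keeps nucleosome -2 in place (no transcribing state reachable)."""
        g = build_pho5_graph(code)
        assert g.n == 6
        assert not is_strongly_connected(g)
        dec = scc_decomposition(g)
        for comp in dec.terminal_components:
            assert all(g.vertex(v).attributes["uasp2"] == "nucleosome" for v in comp)

    def test_no_site_variant_is_inert(self):
        g = build_pho5_graph("XX")
        assert g.n == 4
        assert not is_strongly_connected(g)

    def test_invalid_codes(self):
        with pytest.raises(ValueError):
            build_pho5_graph("ZZ")


class TestLabellingFunctions:
    def test_hill_limits(self):
        assert hill_association(0.0, 25.0, 1.0) == 0.0
        assert hill_association(25.0, 25.0, 1.0) == pytest.approx(0.5)
        assert hill_association(50.0, 25.0, 1.0) == pytest.approx(0.8)

    def test_rapid_equilibrium_fhdc(self):
        assert rapid_equilibrium_label(0.0, 2.0, 1.0, 3.0) == 0.0
        assert rapid_equilibrium_label(3.0, 2.0, 1.0, 3.0) == pytest.approx(1.0)

    def test_rapid_equilibrium_conservation(self):
        Mtot, b, c, L = 2.0, 1.5, 0.6, 0.8
        lm = rapid_equilibrium_label(L, Mtot, b, c)
        m_free = Mtot / (1 + (b / c) * L)
        assert lm + m_free == pytest.approx(Mtot)


class TestTitratableGraphs:
    def test_minimal_chain_attributes(self):
        g = build_titratable_graph(
            [(1, 2, "R", 1.0, 0.5), (2, 3, "U", 2.0, 1.0)], K_R=1.0, R_tot=1.0
        )
        occ = [(v.attributes["R_bound"], v.attributes["U_bound"]) for v in g.vertices]
        assert occ == [(False, False), (True, False), (True, True)]

    def test_double_binding_rejected(self):
        with pytest.raises(ValueError, match="binds twice"):
            build_titratable_graph(
                [(1, 2, "R", 1.0, 0.5), (2, 3, "R", 2.0, 1.0)]
            )

    def test_non_tree_rejected(self):
        with pytest.raises(ValueError, match="tree"):
            build_titratable_graph(
                [(1, 2, "const", 1, 1), (2, 3, "const", 1, 1), (3, 1, "const", 1, 1)]
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tree_satisfies_cycle_condition(self, seed):
        g = _random_titratable_tree(seed, n=7)
        ok, _ = cycle_condition_holds(g, {"S": 2.0})
        assert ok

    def test_r_bound_exactly_downstream_of_r_edge(self):
        g = build_titratable_graph(
            [(1, 2, "const", 1, 1), (2, 3, "R", 1, 1), (3, 4, "U", 1, 1),
             (2, 5, "const", 1, 1)]
        )
        bound = {v.index for v in g.vertices if v.attributes["R_bound"]}
        assert bound == {3, 4}


def _random_titratable_tree(seed, n=7):
    """Random reversible tree with one R edge and one U edge placed on a
    root-to-leaf path, the rest constant."""
    rng = np.random.default_rng(seed)
    parents = {v: int(rng.integers(1, v)) for v in range(2, n + 1)}
    # choose a path from the deepest vertex up to the root for R/U edges
    deepest = n
    path = [deepest]
    while path[-1] != 1:
        path.append(parents[path[-1]])
    kinds = {}
    if len(path) >= 3:
        kinds[(path[-1], path[-2])] = "R"  # edge nearest the root
        kinds[(path[-2], path[-3])] = "U"
    else:
        kinds[(path[-1], path[-2])] = "R"
    specs = []
    for v, u in parents.items():
        kind = kinds.get((u, v), kinds.get((v, u), "const"))
        specs.append((u, v, kind, float(rng.uniform(0.5, 2)), float(rng.uniform(0.5, 2))))
    return build_titratable_graph(specs, K_R=1.0, R_tot=1.0)
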