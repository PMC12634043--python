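"""Core graph model: partitioning, distances, attribute-aware matching."""
import itertools
import math
import random

import networkx as nx
import pytest

from cgweaver.molgraph import (
    Interaction,
    MoleculeGraph,
    connected_components,
    default_node_match,
    graph_distance,
    maximum_common_correspondence,
    subgraph_isomorphisms,
)


def _chain(n, offset=0):
    g = MoleculeGraph()
    for i in range(n):
        g.add_node(offset + i, atom_name=f"A{i}", resname="X", resid=1, element="C")
    for i in range(n - 1):
        g.add_edge(offset + i, offset + i + 1)
    return g


class TestConnectedComponents:
    def test_two_disjoint_chains_partition_into_two_molecules(self):
        g = nx.compose(_chain(3), _chain(3, offset=10))
        mols = connected_components(g)
        assert [len(m) for m in mols] == [3, 3]

    def test_bridge_edge_merges_chains_into_one_molecule(self):
        g = nx.compose(_chain(3), _chain(3, offset=10))
        g.add_edge(2, 10)  # the disulfide-style bridge
        assert len(connected_components(g)) == 1

    def test_isolated_ions_become_single_particle_molecules(self):
        g = MoleculeGraph()
        for i in range(10):
            g.add_node(i, atom_name="NA", resname="NA", resid=i + 1, element="NA")
        mols = connected_components(g)
        assert len(mols) == 10
        assert all(len(m) == 1 for m in mols)

    def test_partitioning_conserves_particles_and_keeps_origin_map(self):
        rng = random.Random(7)
        g = MoleculeGraph()
        for i in range(40):
            g.add_node(i, atom_name=f"A{i}", resname="X", resid=1)
        for _ in range(30):
            g.add_edge(rng.randrange(40), rng.randrange(40))
        mols = connected_components(g)
        assert sum(len(m) for m in mols) == 40
        originals = sorted(
            orig for m in mols for orig in m.graph["orig_ids"].values()
        )
        assert originals == list(range(40))

    def test_empty_graph_yields_no_molecules(self):
        assert connected_components(MoleculeGraph()) == []


class TestGraphDistance:
    def test_path_graph_endpoints(self):
        g = _chain(4)
        assert graph_distance(g, 0, 3) == 3

    def test_distance_to_self_is_zero(self):
        assert graph_distance(_chain(4), 1, 1) == 0

    def test_six_cycle_opposite_nodes(self):
        g = MoleculeGraph()
        g.add_nodes_from((i, {"atom_name": str(i), "resname": "X", "resid": 1}) for i in range(6))
        g.add_edges_from([(i, (i + 1) % 6) for i in range(6)])
        # oracle: breadth-first search
        oracle = nx.shortest_path_length(nx.Graph(g.edges), 0, 3)
        assert graph_distance(g, 0, 3) == oracle == 3

    def test_unknown_node_error_names_the_id(self):
        with pytest.raises(KeyError, match="99"):
            graph_distance(_chain(3), 0, 99)

    def test_disconnected_is_infinite(self):
        g = nx.compose(_chain(2), _chain(2, offset=5))
        assert graph_distance(g, 0, 5) == math.inf

    def test_symmetry_and_triangle_inequality_on_random_graphs(self):
        rng = random.Random(11)
        for _ in range(25):
            n = rng.randint(3, 10)
            g = nx.gnp_random_graph(n, 0.4, seed=rng.randrange(10**6))
            nodes = list(g.nodes)
            a, b, c = rng.choices(nodes, k=3)
            dab = graph_distance(g, a, b)
            dba = graph_distance(g, b, a)
            assert dab == dba
            dac, dcb = graph_distance(g, a, c), graph_distance(g, c, b)
            assert dab <= dac + dcb


def _rand_molgraph(rng, n, p, elements=("C", "N", "O")):
    g = MoleculeGraph()
    for i in range(n):
        g.add_node(i, atom_name=f"A{i}", element=rng.choice(elements), resname="X", resid=1)
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            g.add_edge(i, j)
    return g


def _brute_force_monomorphisms(pattern, target, node_match):
    """Oracle: enumerate every injective assignment outright."""
    pnodes = sorted(pattern.nodes)
    found = []
    for perm in itertools.permutations(sorted(target.nodes), len(pnodes)):
        ok = all(
            node_match(pattern.nodes[p], target.nodes[t])
            for p, t in zip(pnodes, perm)
        )
        if not ok:
            continue
        lookup = dict(zip(pnodes, perm))
        if all(target.has_edge(lookup[u], lookup[v]) for u, v in pattern.edges):
            found.append(lookup)
    return found


class TestSubgraphIsomorphisms:
    def test_single_carbon_pattern_counts_carbons(self):
        pattern = MoleculeGraph()
        pattern.add_node(0, element="C", atom_name="C", resname="X", resid=1)
        target = MoleculeGraph()  # ethane heavy atoms
        target.add_node(0, element="C", atom_name="C1", resname="ETH", resid=1)
        target.add_node(1, element="C", atom_name="C2", resname="ETH", resid=1)
        target.add_edge(0, 1)
        assert len(list(subgraph_isomorphisms(pattern, target))) == 2

    def test_cco_path_in_ethanol_heavy_atoms(self):
        pattern = MoleculeGraph()
        for i, el in enumerate("CCO"):
            pattern.add_node(i, element=el, atom_name=el, resname="X", resid=1)
        pattern.add_edges_from([(0, 1), (1, 2)])
        target = MoleculeGraph()
        for i, (name, el) in enumerate([("C1", "C"), ("C2", "C"), ("O1", "O")]):
            target.add_node(i, element=el, atom_name=name, resname="ETO", resid=1)
        target.add_edges_from([(0, 1), (1, 2)])
        matches = list(subgraph_isomorphisms(pattern, target))
        oracle = _brute_force_monomorphisms(pattern, target, default_node_match)
        assert len(matches) == len(oracle) == 1

    def test_triangle_cannot_embed_in_path(self):
        tri = MoleculeGraph()
        for i in range(3):
            tri.add_node(i, element="C", atom_name=f"C{i}", resname="X", resid=1)
        tri.add_edges_from([(0, 1), (1, 2), (2, 0)])
        path = _chain(4)
        for n in path.nodes:
            path.nodes[n]["element"] = "C"
        assert list(subgraph_isomorphisms(tri, path)) == []

    def test_agrees_with_brute_force_on_random_graphs(self):
        rng = random.Random(5)
        for _ in range(60):
            np_, nt = rng.randint(2, 4), rng.randint(4, 9)
            pattern = _rand_molgraph(rng, np_, 0.5)
            target = _rand_molgraph(rng, nt, 0.35)
            got = {
                tuple(sorted(m.items()))
                for m in subgraph_isomorphisms(pattern, target)
            }
            want = {
                tuple(sorted(m.items()))
                for m in _brute_force_monomorphisms(pattern, target, default_node_match)
            }
            assert got == want

    def test_enumeration_is_deterministic(self):
        rng = random.Random(3)
        pattern = _rand_molgraph(rng, 3, 0.6)
        target = _rand_molgraph(rng, 8, 0.4)
        first = list(subgraph_isomorphisms(pattern, target))
        second = list(subgraph_isomorphisms(pattern, target))
        assert first == second

    def test_cross_check_against_networkx_matcher(self):
        rng = random.Random(17)
        for _ in range(20):
            pattern = _rand_molgraph(rng, 3, 0.6)
            target = _rand_molgraph(rng, 7, 0.4)
            gm = nx.algorithms.isomorphism.GraphMatcher(
                target, pattern,
                node_match=lambda t, p: default_node_match(p, t),
            )
            want = {
                tuple(sorted((p, t) for t, p in m.items()))
                for m in gm.subgraph_monomorphisms_iter()
            }
            got = {
                tuple(sorted(m.items()))
                for m in subgraph_isomorphisms(pattern, target)
            }
            assert got == want


class TestMaximumCommonCorrespondence:
    def test_full_match_when_graphs_identical(self):
        g = _chain(4)
        corr = maximum_common_correspondence(g, g)
        assert len(corr) == 4

    def test_prefers_name_agreement_between_symmetric_matches(self):
        # two carbons symmetric by graph; names break the tie
        pattern = MoleculeGraph()
        pattern.add_node("CA", element="C", atom_name="CA")
        pattern.add_node("CB", element="C", atom_name="CB")
        pattern.add_node("N", element="N", atom_name="N")
        pattern.add_edges_from([("N", "CA"), ("N", "CB")])
        target = MoleculeGraph()
        target.add_node(0, element="N", atom_name="N")
        target.add_node(1, element="C", atom_name="CB")
        target.add_node(2, element="C", atom_name="CA")
        target.add_edges_from([(0, 1), (0, 2)])
        corr = maximum_common_correspondence(pattern, target)
        assert corr["CA"] == 2 and corr["CB"] == 1


class TestInteraction:
    def test_particle_count_must_match_kind(self):
        with pytest.raises(ValueError):
            Interaction("bond", (1, 2, 3))
        with pytest.raises(ValueError):
            Interaction("angle", (1, 2))
        assert Interaction("exclusion", (1, 2, 3)).particles == (1, 2, 3)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            Interaction("torsion", (1, 2, 3, 4))

    def test_interaction_references_must_exist_in_molecule(self):
        g = _chain(2)
        with pytest.raises(KeyError):
            g.add_interaction(Interaction("bond", (0, 99)))
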