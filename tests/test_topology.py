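"""Topology metric battery, power-law fit, MCC hub ranking."""

import itertools
import math
from collections import deque

import networkx as nx
import numpy as np
import pytest

from emtmap.topology import (
    EmptyMapError,
    FitError,
    degree_distribution,
    fit_power_law,
    mcc_scores,
    to_multidigraph,
    top_k_subnetwork,
    topology_report,
    undirected_simple,
)
from emtmap.map_model import RegulatoryMap
from emtmap.synthetic import SyntheticMapSpec, generate_random_map

from conftest import build_map


# ---------------------------------------------------------------------------
# independent brute-force oracles


def bfs_path_stats(adj):
    """(diameter, radius-over-largest-component, cpl) by plain BFS."""
    nodes = list(adj)
    dists = {}
    for s in nodes:
        d = {s: 0}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if v not in d:
                    d[v] = d[u] + 1
                    q.append(v)
        dists[s] = d
    finite = [d for s, dd in dists.items() for t, d in dd.items() if s != t]
    diameter = max(finite) if finite else 0
    cpl = sum(finite) / len(finite) if finite else 0.0
    # components via undirected closure of adj (adj assumed symmetric here)
    seen, comps = set(), []
    for s in nodes:
        if s in seen:
            continue
        comp = set(dists[s])
        comp.add(s)
        stack = [s]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in comp:
                    comp.add(v)
                    stack.append(v)
        seen |= comp
        comps.append(comp)
    largest = max(comps, key=len)
    radii = []
    for s in largest:
        ecc = max((d for t, d in dists[s].items() if t != s), default=0)
        if ecc > 0:
            radii.append(ecc)
    radius = min(radii) if radii else 0
    return diameter, radius, cpl


def brute_mcc(U):
    """MCC by enumerating every vertex subset and filtering maximal cliques."""
    nodes = list(U.nodes)
    n = len(nodes)
    cliques = []
    for r in range(2, n + 1):
        for comb in itertools.combinations(nodes, r):
            if all(U.has_edge(a, b) for a, b in itertools.combinations(comb, 2)):
                cliques.append(set(comb))
    maximal = [c for c in cliques if not any(c < d for d in cliques)]
    scores = {v: 0 for v in nodes}
    for c in maximal:
        w = math.factorial(len(c) - 1)
        for v in c:
            scores[v] += w
    return scores


def triangle_map():
    return build_map(
        [("A", "activation", "B"), ("B", "activation", "C"), ("C", "activation", "A")]
    )


class TestTopologyReport:
    def test_triangle_undirected(self):
        rep = topology_report(triangle_map(), "undirected")
        assert rep.clustering_coefficient == 1.0
        assert rep.diameter == 1
        assert rep.n_connected_components == 1
        assert rep.density == 1.0

    def test_three_node_path(self):
        rep = topology_report(build_map([("A", "activation", "B"), ("B", "activation", "C")]), "undirected")
        assert rep.diameter == 2
        assert rep.characteristic_path_length == pytest.approx(4 / 3)

    def test_empty_map_rejected(self):
        with pytest.raises(EmptyMapError):
            topology_report(RegulatoryMap(), "undirected")

    def test_parallel_edges_counted_then_merged(self):
        m = build_map([("A", "activation", "B"), ("A", "inhibition", "B"), ("B", "activation", "C")])
        rep = topology_report(m, "undirected")
        assert rep.multi_edge_node_pairs == 1
        assert rep.n_edges == 2  # merged simple view

    def test_matches_bfs_oracle_on_random_graphs(self):
        for seed in range(40):
            m = generate_random_map(
                SyntheticMapSpec(n_nodes=5 + seed % 8, n_edges=8 + seed % 9, inhibition_fraction=0.3, seed=seed)
            )
            rep = topology_report(m, "undirected")
            U = undirected_simple(to_multidigraph(m))
            adj = {u: set(U.neighbors(u)) for u in U}
            dia, rad, cpl = bfs_path_stats(adj)
            assert rep.diameter == dia
            assert rep.radius == rad
            assert rep.characteristic_path_length == pytest.approx(cpl)
            assert rep.n_connected_components == nx.number_connected_components(U)

    def test_mode_consistency(self):
        for seed in (1, 2, 3):
            m = generate_random_map(SyntheticMapSpec(n_nodes=12, n_edges=25, seed=seed))
            und = topology_report(m, "undirected")
            dir_ = topology_report(m, "directed")
            assert und.n_edges <= dir_.n_edges
            assert und.n_connected_components == dir_.n_connected_components

    def test_relabelling_permutes_report_invariantly(self):
        m = generate_random_map(SyntheticMapSpec(n_nodes=10, n_edges=18, seed=4))
        relabel = {n: f"x_{n}" for n in m.species_ids()}
        from emtmap.map_model import Interaction, SpeciesNode

        m2 = RegulatoryMap(
            [SpeciesNode(relabel[s.id], s.name) for s in m.species],
            [
                Interaction(i.id, tuple(relabel[s] for s in i.sources), relabel[i.target], i.category, i.sign)
                for i in m.interactions
            ],
        )
        a, b = topology_report(m, "undirected"), topology_report(m2, "undirected")
        assert (a.diameter, a.radius, a.characteristic_path_length) == (
            b.diameter,
            b.radius,
            b.characteristic_path_length,
        )
        sa, sb = mcc_scores(m).scores, mcc_scores(m2).scores
        assert {relabel[k]: v for k, v in sa.items()} == sb


class TestDegreeAndPowerLaw:
    def test_star_has_two_occupied_degrees(self):
        m = build_map([(f"L{i}", "activation", "HUB") for i in range(10)])
        dd = degree_distribution(m, "undirected")
        assert dd.counts == {1: 10, 10: 1}
        assert dd.n_nodes == 11

    def test_too_few_occupied_degrees_rejected(self):
        m = triangle_map()
        with pytest.raises(FitError):
            fit_power_law(degree_distribution(m, "undirected"))

    def test_exact_power_law_histogram_recovered(self):
        """On counts that ARE a power law, the fit returns the exponent exactly."""
        from emtmap.topology import DegreeDistribution

        counts = {d: int(round(10_000 * d ** -2.5)) for d in (1, 2, 4, 8, 16)}
        fit = fit_power_law(DegreeDistribution(counts, "undirected", "total"))
        # integer rounding of the counts perturbs the slope slightly
        assert fit.exponent == pytest.approx(2.5, abs=0.01)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-3)

    def test_preferential_attachment_graph_looks_scale_free(self):
        # raw-histogram least squares on a finite graph underestimates the
        # theoretical exponent of 3; the check is for a credible power law
        G = nx.barabasi_albert_graph(2000, 2, seed=42)
        edges = [(f"n{u}", "activation", f"n{v}") for u, v in G.edges()]
        m = build_map(edges)
        fit = fit_power_law(degree_distribution(m, "undirected"))
        assert 1.5 <= fit.exponent <= 3.5
        assert fit.r_squared >= 0.7


class TestMcc:
    def test_triangle_every_node_two(self):
        assert set(mcc_scores(triangle_map()).scores.values()) == {2}

    def test_star_centre_counts_its_edges(self):
        m = build_map([("L1", "activation", "H"), ("L2", "activation", "H"), ("L3", "activation", "H")])
        scores = mcc_scores(m).scores
        assert scores["H"] == 3
        assert scores["L1"] == scores["L2"] == scores["L3"] == 1

    def test_complete_graph_k4(self):
        edges = [(a, "activation", b) for a, b in itertools.combinations("ABCD", 2)]
        assert set(mcc_scores(build_map(edges)).scores.values()) == {math.factorial(3)}

    def test_matches_bruteforce_on_random_graphs(self):
        for seed in range(30):
            m = generate_random_map(
                SyntheticMapSpec(n_nodes=5 + seed % 6, n_edges=8 + seed % 10, inhibition_fraction=0.3, seed=seed)
            )
            U = undirected_simple(to_multidigraph(m))
            assert mcc_scores(m).scores == brute_mcc(U)

    def test_ranking_tie_break_is_lexicographic(self):
        m = build_map([("A", "activation", "B"), ("C", "activation", "D")])
        ranking = mcc_scores(m)
        assert ranking.ranked == ["A", "B", "C", "D"]


class TestTopK:
    def test_k_equals_n_returns_whole_map(self, emt_map):
        ranking = mcc_scores(emt_map)
        sub = top_k_subnetwork(ranking, emt_map.n_species, emt_map)
        assert sub.n_species == emt_map.n_species
        assert sub.n_interactions == emt_map.n_interactions

    def test_k_one_on_star_is_centre_only(self):
        m = build_map([("L1", "activation", "H"), ("L2", "activation", "H")])
        sub = top_k_subnetwork(mcc_scores(m), 1, m)
        assert sub.species_ids() == ["H"]
        assert sub.n_interactions == 0

    def test_k_out_of_range_rejected(self, emt_map):
        ranking = mcc_scores(emt_map)
        with pytest.raises(ValueError):
            top_k_subnetwork(ranking, 0, emt_map)
        with pytest.raises(ValueError):
            top_k_subnetwork(ranking, emt_map.n_species + 1, emt_map)

    def test_signs_preserved_in_submap(self, emt_map):
        sub = top_k_subnetwork(mcc_scores(emt_map), 10, emt_map)
        orig = {(i.sources, i.target): i.sign for i in emt_map.interactions}
        for i in sub.interactions:
            assert orig[(i.sources, i.target)] == i.sign
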