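"""Topological characterisation of regulatory maps.

The metric battery mirrors what network-analysis tools report for disease
maps: node/edge counts, average neighbourhood size, diameter, radius,
characteristic path length, clustering coefficient, density, connected
components, multi-edge node pairs, self-loops — on a directed or an
undirected view of the map.  Shortest-path statistics are taken over
connected node pairs only (disease maps are usually disconnected), the
radius over the largest component.  Hubs are ranked by Maximal Clique
Centrality: MCC(v) = Σ over maximal cliques C containing v of (|C|−1)!,
computed on the undirected simple projection by Bron–Kerbosch enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np

from .map_model import Interaction, RegulatoryMap


class EmptyMapError(ValueError):
    pass


class FitError(ValueError):
    pass


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    avg_neighbours: float
    diameter: int
    radius: int
    characteristic_path_length: float
    clustering_coefficient: float
    density: float
    n_connected_components: int
    multi_edge_node_pairs: int
    n_self_loops: int
    mode: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class DegreeDistribution:
    counts: dict[int, int]  # degree -> number of nodes
    mode: str
    direction: str  # in | out | total

    @property
    def n_nodes(self) -> int:
        return sum(self.counts.values())


@dataclass
class PowerLawFit:
    exponent: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass
class HubRanking:
    scores: dict[str, int]
    ranked: list[str]

    def top(self, k: int) -> list[str]:
        return self.ranked[:k]


# ---------------------------------------------------------------------------
# graph views


def to_multidigraph(map_: RegulatoryMap, include_degradation: bool = False) -> nx.MultiDiGraph:
    """Directed multigraph view: one edge per (source, target) of each
    interaction; degradation sinks excluded by default."""
    skip = {
        s.id for s in map_.species if s.kind == "degradation" and not include_degradation
    }
    G = nx.MultiDiGraph()
    for s in map_.species:
        if s.id not in skip:
            G.add_node(s.id, kind=s.kind)
    for inter in map_.interactions:
        if inter.target in skip:
            continue
        for src in inter.sources:
            if src in skip:
                continue
            G.add_edge(src, inter.target, sign=inter.sign, interaction=inter.id)
    return G


def undirected_simple(G: nx.MultiDiGraph, drop_self_loops: bool = True) -> nx.Graph:
    U = nx.Graph()
    U.add_nodes_from(G.nodes)
    for u, v in G.edges():
        if drop_self_loops and u == v:
            continue
        U.add_edge(u, v)
    return U


# ---------------------------------------------------------------------------
# metric battery


def _path_stats(G: nx.Graph | nx.DiGraph) -> tuple[int, int, float]:
    """(diameter, radius, characteristic path length) over connected pairs.

    Eccentricities use only pairs with a finite distance; the radius is the
    smallest eccentricity within the largest connected component (isolated
    nodes would otherwise force a radius of 0 on any disconnected map).
    """
    directed = G.is_directed()
    dists = dict(nx.all_pairs_shortest_path_length(G))
    total = 0
    n_pairs = 0
    diameter = 0
    ecc: dict[str, int] = {}
    for u, targets in dists.items():
        e = 0
        for v, d in targets.items():
            if u == v:
                continue
            total += d
            n_pairs += 1
            e = max(e, d)
            diameter = max(diameter, d)
        ecc[u] = e
    cpl = total / n_pairs if n_pairs else 0.0
    if directed:
        comps = list(nx.weakly_connected_components(G))
    else:
        comps = list(nx.connected_components(G))
    largest = max(comps, key=len) if comps else set()
    radii = [ecc[u] for u in largest if ecc[u] > 0]
    radius = min(radii) if radii else 0
    return diameter, radius, cpl


def topology_report(map_: RegulatoryMap, mode: str = "undirected") -> TopologyReport:
    """Compute the full metric battery on one view of the map."""
    if map_.n_species == 0:
        raise EmptyMapError("cannot analyse an empty map")
    if mode not in ("directed", "undirected"):
        raise ValueError(f"unknown mode {mode!r}")
    M = to_multidigraph(map_)
    n_self = sum(1 for u, v in M.edges() if u == v)

    if mode == "undirected":
        # count parallel edges (ignoring direction) before merging
        pair_counts: dict[frozenset, int] = {}
        for u, v in M.edges():
            if u == v:
                continue
            key = frozenset((u, v))
            pair_counts[key] = pair_counts.get(key, 0) + 1
        multi_pairs = sum(1 for c in pair_counts.values() if c > 1)
        U = undirected_simple(M)
        diameter, radius, cpl = _path_stats(U)
        n = U.number_of_nodes()
        e = U.number_of_edges()
        avg_neigh = float(np.mean([d for _, d in U.degree()])) if n else 0.0
        clustering = nx.average_clustering(U) if n else 0.0
        density = 2 * e / (n * (n - 1)) if n > 1 else 0.0
        n_comp = nx.number_connected_components(U)
    else:
        pair_counts = {}
        for u, v in M.edges():
            if u == v:
                continue
            key = (u, v)
            pair_counts[key] = pair_counts.get(key, 0) + 1
        multi_pairs = sum(1 for c in pair_counts.values() if c > 1)
        D = nx.DiGraph()
        D.add_nodes_from(M.nodes)
        D.add_edges_from((u, v) for u, v in M.edges() if u != v)
        diameter, radius, cpl = _path_stats(D)
        n = D.number_of_nodes()
        e = D.number_of_edges()
        avg_neigh = (
            float(np.mean([len(set(D.successors(u)) | set(D.predecessors(u))) for u in D]))
            if n
            else 0.0
        )
        Dsl = nx.DiGraph(D)  # self-loops already excluded
        clustering = nx.average_clustering(Dsl) if n else 0.0
        density = e / (n * (n - 1)) if n > 1 else 0.0
        n_comp = nx.number_weakly_connected_components(D)

    return TopologyReport(
        n_nodes=n,
        n_edges=e,
        avg_neighbours=avg_neigh,
        diameter=diameter,
        radius=radius,
        characteristic_path_length=cpl,
        clustering_coefficient=clustering,
        density=density,
        n_connected_components=n_comp,
        multi_edge_node_pairs=multi_pairs,
        n_self_loops=n_self,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# degree distribution and power-law check


def degree_distribution(
    map_: RegulatoryMap, mode: str = "undirected", direction: str = "total"
) -> DegreeDistribution:
    M = to_multidigraph(map_)
    if mode == "undirected":
        U = undirected_simple(M)
        degs = [d for _, d in U.degree()]
    else:
        D = nx.DiGraph()
        D.add_nodes_from(M.nodes)
        D.add_edges_from((u, v) for u, v in M.edges() if u != v)
        if direction == "in":
            degs = [d for _, d in D.in_degree()]
        elif direction == "out":
            degs = [d for _, d in D.out_degree()]
        else:
            degs = [D.in_degree(u) + D.out_degree(u) for u in D]
    counts: dict[int, int] = {}
    for d in degs:
        counts[d] = counts.get(d, 0) + 1
    return DegreeDistribution(counts=counts, mode=mode, direction=direction)


def fit_power_law(dd: DegreeDistribution) -> PowerLawFit:
    """Least-squares line on log10(degree) vs log10(count), non-zero bins.

    The fitted exponent is the negative slope; r² measures how well the
    log-log histogram is described by a line (a scale-free check, not a
    rigorous maximum-likelihood tail fit).
    """
    pts = [(d, c) for d, c in dd.counts.items() if d > 0 and c > 0]
    if len(pts) < 3:
        raise FitError(f"need >= 3 occupied degrees, got {len(pts)}")
    x = np.log10([d for d, _ in pts])
    y = np.log10([c for _, c in pts])
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(exponent=-float(slope), intercept=float(intercept), r_squared=r2, n_points=len(pts))


# ---------------------------------------------------------------------------
# MCC hub ranking


def mcc_scores(map_: RegulatoryMap) -> HubRanking:
    """Maximal Clique Centrality on the undirected simple projection.

    MCC(v) = Σ over maximal cliques C with v ∈ C and |C| ≥ 2 of (|C|−1)!.
    A node whose only maximal cliques are single edges therefore scores the
    number of those edges; isolated nodes score 0.  Ranking is by
    descending score with lexicographic id tie-break.
    """
    if map_.n_species == 0:
        raise EmptyMapError("cannot rank an empty map")
    U = undirected_simple(to_multidigraph(map_))
    scores = {n: 0 for n in U.nodes}
    for clique in nx.find_cliques(U):
        if len(clique) < 2:
            continue
        w = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    ranked = sorted(scores, key=lambda v: (-scores[v], v))
    return HubRanking(scores=scores, ranked=ranked)


def top_k_subnetwork(ranking: HubRanking, k: int, map_: RegulatoryMap) -> RegulatoryMap:
    """Induced sub-map on the k top-ranked nodes, signs preserved."""
    if not 1 <= k <= len(ranking.ranked):
        raise ValueError(f"k={k} outside [1, {len(ranking.ranked)}]")
    keep = set(ranking.top(k))
    species = [s for s in map_.species if s.id in keep]
    interactions = [
        i
        for i in map_.interactions
        if i.target in keep and all(s in keep for s in i.sources)
    ]
    return RegulatoryMap(species, interactions, provenance=f"{map_.provenance}#top{k}")
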