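"""Topology summaries and two-network comparison.

Used to contrast condition-specific interaction networks (e.g. tumor vs
normal): global topology metrics, node/edge overlap fractions with the
first network as the reference denominator, per-gene degree shifts on the
shared genes, seed-gene neighborhood extraction and a descriptive log-log
degree-distribution slope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network_assembly import GGINetwork

logger = logging.getLogger(__name__)


def _as_graph(g) -> nx.Graph:
    return g.graph if isinstance(g, GGINetwork) else g


@dataclass
class TopologySummary:
    """Global metrics of a simple undirected graph.

    Path metrics are computed within connected components: the
    characteristic path length is the mean shortest-path distance over all
    connected node pairs, the diameter the largest finite distance.
    """

    n_nodes: int
    n_edges: int
    degree_sequence: list[int]
    characteristic_path_length: float
    diameter: int
    average_clustering: float
    n_components: int
    empty: bool = False


def topology_summary(g) -> TopologySummary:
    graph = _as_graph(g)
    if graph.number_of_nodes() == 0:
        logger.warning("topology_summary on an empty graph")
        return TopologySummary(0, 0, [], 0.0, 0, 0.0, 0, empty=True)
    degrees = sorted((d for _, d in graph.degree()), reverse=True)
    total_dist = 0
    n_pairs = 0
    diameter = 0
    for node, dists in nx.all_pairs_shortest_path_length(graph):
        for other, dist in dists.items():
            if other != node:
                total_dist += dist
                n_pairs += 1
                diameter = max(diameter, dist)
    cpl = total_dist / n_pairs if n_pairs else 0.0
    clustering = nx.average_clustering(graph) if graph.number_of_nodes() else 0.0
    return TopologySummary(
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        degree_sequence=degrees,
        characteristic_path_length=cpl,
        diameter=diameter,
        average_clustering=clustering,
        n_components=nx.number_connected_components(graph),
    )


@dataclass
class ComparisonReport:
    """Asymmetric overlap of network ``a`` against network ``b``.

    Fractions use network a's node/edge counts as denominators; degree
    deltas are computed on the shared nodes (up = higher degree in a).
    """

    node_overlap: float
    edge_overlap: float
    shared_nodes: list[str]
    up_genes: list[str]
    down_genes: list[str]
    unchanged_genes: list[str]


def compare_networks(a, b) -> ComparisonReport:
    ga, gb = _as_graph(a), _as_graph(b)
    if ga.number_of_nodes() == 0:
        raise ValueError("reference network (a) has no nodes")
    shared = sorted(set(ga.nodes) & set(gb.nodes))
    node_overlap = len(shared) / ga.number_of_nodes()
    edges_a = {tuple(sorted(e)) for e in ga.edges()}
    edges_b = {tuple(sorted(e)) for e in gb.edges()}
    edge_overlap = len(edges_a & edges_b) / len(edges_a) if edges_a else 0.0
    up, down, unchanged = [], [], []
    for node in shared:
        da, db = ga.degree(node), gb.degree(node)
        (up if da > db else down if da < db else unchanged).append(node)
    return ComparisonReport(node_overlap, edge_overlap, shared, up, down, unchanged)


def neighborhood_extract(g, seeds: list[str]) -> GGINetwork:
    """Induced subgraph on the seed genes present in ``g`` plus their direct
    neighbors. Seeds missing from the network are logged (and recorded under
    ``graph.graph["missing_seeds"]``), not errors."""
    if not seeds:
        raise ValueError("seed list must be non-empty")
    graph = _as_graph(g)
    present = [s for s in seeds if s in graph]
    missing = [s for s in seeds if s not in graph]
    if missing:
        logger.warning("%d seed gene(s) absent from the network: %s",
                       len(missing), ", ".join(missing[:10]))
    keep: set[str] = set(present)
    for s in present:
        keep.update(graph[s])
    sub = graph.subgraph(keep).copy()
    sub.graph["missing_seeds"] = missing
    sub.graph["seed_genes"] = present
    return GGINetwork(graph=sub)


@dataclass
class DegreeDistributionFit:
    """Degree histogram plus a descriptive least-squares log-log slope.

    ``slope`` is None (with ``flagged`` giving the reason) when the graph is
    too small or has fewer than two distinct nonzero degrees; no statistical
    power-law test is implied.
    """

    histogram: dict[int, int]
    slope: float | None
    intercept: float | None
    flagged: str | None = None


def degree_distribution_fit(g, min_nodes: int = 10) -> DegreeDistributionFit:
    graph = _as_graph(g)
    degrees = [d for _, d in graph.degree()]
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    hist = dict(sorted(hist.items()))
    flagged = None
    if graph.number_of_nodes() < min_nodes:
        flagged = f"graph has fewer than {min_nodes} nodes; histogram only"
        logger.warning(flagged)
        return DegreeDistributionFit(hist, None, None, flagged)
    pts = [(k, c) for k, c in hist.items() if k > 0]
    if len(pts) < 2:
        flagged = "fewer than two distinct nonzero degrees; slope undefined"
        logger.warning(flagged)
        return DegreeDistributionFit(hist, None, None, flagged)
    x = np.log10([k for k, _ in pts])
    y = np.log10([c for _, c in pts])
    slope, intercept = np.polyfit(x, y, 1)
    return DegreeDistributionFit(hist, float(slope), float(intercept), None)
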