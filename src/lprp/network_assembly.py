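"""Backbone-constrained assembly of the final gene-gene interaction network.

Assembly runs in three stages. *Raw construction* keeps exactly the
validated interactions that are also backbone (KP) edges — orientation is
irrelevant since both graphs are undirected. The remaining validated
interactions ("leftovers") are then worked through alternating *expansion*
and *revision* cycles until a full cycle adds nothing:

* expansion attaches every leftover with exactly one endpoint already in
  the network (category c), bringing in its new endpoint;
* revision considers leftovers whose endpoints are both present (category
  a, plus pairs whose endpoints arrived in this cycle's expansion) and
  attaches those sharing strictly more than ``omega`` common neighbors in
  the current network; an edge failing the test stays leftover and is
  retried in later cycles, since growing neighborhoods can later satisfy it;
* leftovers with neither endpoint present (category b) stay deferred and
  are discarded at termination.

Within each stage, edges are evaluated in canonical lexicographic order
against a snapshot of the network taken at stage start; additions become
visible at the next stage. This makes the result independent of processing
order inside a stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .interaction_detection import CandidateInteraction

DEFAULT_OMEGA = 1


@dataclass
class ProvenanceEntry:
    """One edge addition: which cycle, which stage, and — for revised edges —
    the common-neighbor count that admitted it."""

    cycle: int
    stage: str
    gene_a: str
    gene_b: str
    common_neighbors: int | None = None


@dataclass
class GGINetwork:
    """Undirected simple graph of inferred gene-gene interactions.

    Every edge carries ``type`` (con/re), ``score``, ``p_value`` and
    ``stage`` (raw/expanded/revised) attributes; ``provenance`` logs each
    addition in order and ``discarded`` holds validated interactions that
    never attached.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    provenance: list[ProvenanceEntry] = field(default_factory=list)
    discarded: list[CandidateInteraction] = field(default_factory=list)

    def add_interaction(self, c: CandidateInteraction, stage: str, cycle: int,
                        common_neighbors: int | None = None) -> None:
        self.graph.add_edge(c.gene_a, c.gene_b, type=c.reg_type, score=c.score,
                            p_value=c.p_value, stage=stage)
        self.provenance.append(ProvenanceEntry(cycle, stage, c.gene_a, c.gene_b,
                                               common_neighbors))

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges()}


def build_raw(validated: list[CandidateInteraction], kp: nx.Graph
              ) -> tuple[GGINetwork, list[CandidateInteraction]]:
    """Intersect validated interactions with the backbone.

    Returns the raw network (stage ``raw``, cycle 0) and the leftover
    interactions not covered by the backbone, both in canonical order.
    """
    net = GGINetwork()
    leftover: list[CandidateInteraction] = []
    for c in sorted(validated, key=lambda c: c.pair):
        if kp.has_edge(c.gene_a, c.gene_b):
            net.add_interaction(c, "raw", 0)
        else:
            leftover.append(c)
    return net, leftover


def common_neighbor_count(g: GGINetwork | nx.Graph, a: str, b: str) -> int:
    """|N(a) ∩ N(b)| in the current network; absent nodes have no neighbors."""
    if a == b:
        raise ValueError("common neighbors require two distinct genes")
    graph = g.graph if isinstance(g, GGINetwork) else g
    if a not in graph or b not in graph:
        return 0
    return len(set(graph[a]) & set(graph[b]))


def expand_revise(net: GGINetwork, leftover: list[CandidateInteraction],
                  kp: nx.Graph, omega: int = DEFAULT_OMEGA) -> GGINetwork:
    """Alternate expansion and revision until a full cycle adds nothing.

    Mutates and returns ``net``. Unattached leftovers at termination are
    recorded in ``net.discarded``.
    """
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    pending = sorted(leftover, key=lambda c: c.pair)
    cycle = 0
    while True:
        cycle += 1
        added = 0

        # Expansion: attach one-endpoint edges, judged against the node set
        # as it stood when the stage began.
        snapshot_nodes = set(net.graph.nodes)
        still: list[CandidateInteraction] = []
        for c in pending:
            inside = (c.gene_a in snapshot_nodes) + (c.gene_b in snapshot_nodes)
            if inside == 1:
                net.add_interaction(c, "expanded", cycle)
                added += 1
            else:
                still.append(c)
        pending = still

        # Revision: both endpoints present (including nodes attached by this
        # cycle's expansion); admit when the common-neighbor count in the
        # revision-start snapshot strictly exceeds omega.
        snapshot = net.graph.copy()
        still = []
        for c in pending:
            if c.gene_a in snapshot and c.gene_b in snapshot:
                cn = common_neighbor_count(snapshot, c.gene_a, c.gene_b)
                if cn > omega:
                    net.add_interaction(c, "revised", cycle, common_neighbors=cn)
                    added += 1
                    continue
            still.append(c)
        pending = still

        if added == 0:
            break
    net.discarded.extend(pending)
    return net


def assemble(validated: list[CandidateInteraction], kp: nx.Graph,
             omega: int = DEFAULT_OMEGA) -> GGINetwork:
    """Full assembly: raw backbone intersection, then expansion/revision."""
    net, leftover = build_raw(validated, kp)
    return expand_revise(net, leftover, kp, omega=omega)


def write_assembly_log(net: GGINetwork, path) -> None:
    """TSV log: one line per added edge (cycle, stage, genes, common-neighbor
    count for revised edges) followed by discarded leftovers."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("cycle\tstage\tgene_a\tgene_b\tcommon_neighbors\n")
        for e in net.provenance:
            cn = "" if e.common_neighbors is None else str(e.common_neighbors)
            fh.write(f"{e.cycle}\t{e.stage}\t{e.gene_a}\t{e.gene_b}\t{cn}\n")
        for c in net.discarded:
            fh.write(f"\tdiscarded\t{c.gene_a}\t{c.gene_b}\t\n")
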