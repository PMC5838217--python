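"""Synthetic ground-truth networks, expression matrices and backbones.

The generator replaces downloaded expression compendia and curated
protein-interaction backbones with a controllable test substrate:

* a signed truth network (edge sign +1 = forward/co-varying, -1 =
  reverse/anti-varying regulation);
* expression profiles whose ternary latent structure follows the truth
  network — every connected component shares a per-sample driver state and
  each gene copies the driver (or its sign flip) according to the product
  of edge signs along a spanning tree, with independent per-gene flip
  noise — then mapped to real values in three well-separated bands so that
  the standard gamma = 0.45 discretization recovers the latent states with
  high probability;
* a backbone covering a tunable fraction of the truth edges plus decoy
  pairs, standing in for a curated interaction network that is neither
  complete nor perfectly clean.

Because the latent state is shared component-wide, *all* gene pairs inside
a component are statistically dependent, not only the pairs joined by a
truth edge — exactly the transitive co-expression structure that makes the
backbone intersection step necessary on real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .expression_io import ExpressionMatrix

# Real-value band centers for latent states -1/0/1; separation is large
# relative to the default jitter so the gamma-band discretization recovers
# the latent state unless a row's state mix is extremely skewed.
BAND_CENTERS = {-1: 2.0, 0: 6.0, 1: 10.0}
DEFAULT_JITTER = 0.5


@dataclass
class TruthNetwork:
    """Signed ground-truth regulatory network.

    ``graph`` is simple and undirected; each edge carries ``sign`` (+1
    forward, -1 reverse).
    """

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges_signed(self) -> list[tuple[str, str, int]]:
        return sorted((min(a, b), max(a, b), d["sign"])
                      for a, b, d in self.graph.edges(data=True))

    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges()}


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_truth(n_genes: int, n_edges: int, reverse_fraction: float,
                   rng: np.random.Generator) -> TruthNetwork:
    """Uniformly sampled simple graph with randomly signed edges."""
    max_edges = n_genes * (n_genes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"{n_edges} edges infeasible for {n_genes} genes "
                         f"(max {max_edges})")
    if not 0.0 <= reverse_fraction <= 1.0:
        raise ValueError("reverse_fraction must be in [0, 1]")
    g = nx.Graph()
    g.add_nodes_from(_gene_name(i) for i in range(n_genes))
    chosen = rng.choice(max_edges, size=n_edges, replace=False)
    iu, ju = np.triu_indices(n_genes, k=1)
    signs = np.where(rng.random(n_edges) < reverse_fraction, -1, 1)
    for k, s in zip(chosen, signs):
        g.add_edge(_gene_name(iu[k]), _gene_name(ju[k]), sign=int(s))
    return TruthNetwork(g)


def _polarities(t: TruthNetwork) -> dict[str, int]:
    """Assign each gene a +/-1 polarity via a spanning tree from each
    component's lexicographically first node: a gene's polarity is the
    product of edge signs on its tree path to the root. Edges on cycles
    with an odd number of reverse signs are frustrated — their realized
    relation is the polarity product, which may disagree with the nominal
    sign — but the pair remains perfectly dependent either way."""
    pol: dict[str, int] = {}
    for comp in nx.connected_components(t.graph):
        root = min(comp)
        pol[root] = 1
        for parent, child in nx.bfs_edges(t.graph, root):
            pol[child] = pol[parent] * t.graph.edges[parent, child]["sign"]
    return pol


def simulate_expression(t: TruthNetwork, n_samples: int, flip_noise: float,
                        rng: np.random.Generator,
                        jitter: float = DEFAULT_JITTER) -> ExpressionMatrix:
    """Expression matrix whose discretized states realize the truth network.

    Per sample, each connected component draws a driver state uniformly
    from {-1, 0, 1}; each gene's latent state is the driver times the
    gene's polarity. With probability ``flip_noise`` a gene's latent state
    in a sample is replaced by an independent uniform draw. Latent states
    map to values drawn uniformly within jitter of three fixed band
    centers (low/mid/high), all non-negative.
    """
    if not 0.0 <= flip_noise <= 0.5:
        raise ValueError("flip_noise must be in [0, 0.5]")
    genes = t.nodes
    pol = _polarities(t)
    comps = {g: k for k, comp in enumerate(nx.connected_components(t.graph))
             for g in comp}
    n_comp = max(comps.values()) + 1 if comps else 0
    drivers = rng.integers(-1, 2, size=(n_comp, n_samples))
    latent = np.empty((len(genes), n_samples), dtype=np.int8)
    for gi, g in enumerate(genes):
        latent[gi] = pol[g] * drivers[comps[g]]
    flip = rng.random(latent.shape) < flip_noise
    latent[flip] = rng.integers(-1, 2, size=int(flip.sum()))
    centers = np.array([BAND_CENTERS[-1], BAND_CENTERS[0], BAND_CENTERS[1]])
    values = centers[latent.astype(int) + 1] + rng.uniform(-jitter, jitter,
                                                           size=latent.shape)
    sample_ids = [f"S{j:04d}" for j in range(n_samples)]
    return ExpressionMatrix(list(genes), sample_ids, values)


def generate_backbone(t: TruthNetwork, true_coverage: float, n_decoys: int,
                      rng: np.random.Generator) -> nx.Graph:
    """Backbone = a fixed fraction of (unsigned) truth edges plus decoys.

    Exactly ``round(true_coverage * |E|)`` truth edges are kept and
    ``n_decoys`` non-truth pairs added, both sampled uniformly without
    replacement.
    """
    if not 0.0 <= true_coverage <= 1.0:
        raise ValueError("true_coverage must be in [0, 1]")
    truth_edges = sorted(t.edge_set())
    n_keep = int(round(true_coverage * len(truth_edges)))
    keep_idx = rng.choice(len(truth_edges), size=n_keep, replace=False) \
        if truth_edges else np.array([], dtype=int)
    genes = t.nodes
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    name = {g: k for k, g in enumerate(genes)}
    truth_condensed = set()
    offsets = np.concatenate(([0], np.cumsum(np.arange(n - 1, 0, -1))))
    for a, b in truth_edges:
        i, j = sorted((name[a], name[b]))
        truth_condensed.add(int(offsets[i] + (j - i - 1)))
    n_pairs = n * (n - 1) // 2
    available = n_pairs - len(truth_condensed)
    if n_decoys > available:
        raise ValueError(f"requested {n_decoys} decoys but only {available} "
                         "non-truth pairs exist")
    kp = nx.Graph()
    for k in sorted(keep_idx):
        kp.add_edge(*truth_edges[k])
    # Rejection-sample decoy pairs from the condensed index space.
    decoys: set[int] = set()
    while len(decoys) < n_decoys:
        draw = rng.integers(0, n_pairs, size=max(4 * (n_decoys - len(decoys)), 16))
        for k in draw:
            k = int(k)
            if k not in truth_condensed and k not in decoys:
                decoys.add(k)
                if len(decoys) == n_decoys:
                    break
    for k in sorted(decoys):
        kp.add_edge(genes[iu[k]], genes[ju[k]])
    return kp


def write_fixtures(t: TruthNetwork, expr: ExpressionMatrix, kp: nx.Graph,
                   out_dir: str | Path) -> dict[str, Path]:
    """Write expr.tsv, truth.sif (relation = con/re by sign) and kp.sif."""
    from .expression_io import write_backbone, write_expression_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"expression": out / "expr.tsv", "truth": out / "truth.sif",
             "backbone": out / "kp.sif"}
    write_expression_matrix(expr, paths["expression"])
    with paths["truth"].open("w") as fh:
        for a, b, sign in t.edges_signed():
            fh.write(f"{a}\t{'con' if sign > 0 else 're'}\t{b}\n")
    write_backbone(kp, paths["backbone"])
    return paths
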