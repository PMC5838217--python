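"""Permutation null model and edge-level significance.

The null preserves each gene's marginal state distribution while destroying
all cross-gene structure: every row of the discretized matrix is
independently shuffled across samples. Scoring is repeated on many such
shuffled matrices (1000 in the reference protocol) and, for each gene pair,
T_appear counts the replicates in which the pair passes the theta filter as
either con or re (regulation type is ignored when counting appearances).
The p-value is (T_appear + 1) / replicates — for 1000 replicates this is
the published (T_appear + 1)/1000 rule; note the conventional permutation
p-value would divide by replicates + 1 instead, a deliberate difference
kept for fidelity to the published procedure. Candidates survive when
p < alpha (strict by default, alpha = 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .discretization import DiscretizedMatrix
from .interaction_detection import (
    CandidateInteraction,
    _classify_counts,
    _edge_count_stats,
    condensed_pair_indices,
    pair_count_stats,
)

DEFAULT_REPLICATES = 1000
DEFAULT_ALPHA = 0.01


def shuffle_rows(d: DiscretizedMatrix, rng: np.random.Generator) -> DiscretizedMatrix:
    """Independently permute each gene's states across samples.

    Every row keeps its multiset of -1/0/1 states, so the marginal
    distribution of each gene is exactly preserved.
    """
    return DiscretizedMatrix(list(d.gene_ids), list(d.sample_ids),
                             rng.permuted(d.states, axis=1))


@dataclass
class NullCensus:
    """Appearance counts of gene pairs across permutation replicates.

    ``appearance`` stores only pairs seen at least once; any pair absent
    from the map has T_appear = 0.
    """

    replicates: int
    appearance: dict[tuple[str, str], int]
    rng_seed: int
    theta: float

    def t_appear(self, gene_a: str, gene_b: str) -> int:
        key = (gene_a, gene_b) if gene_a < gene_b else (gene_b, gene_a)
        return self.appearance.get(key, 0)


def null_census(d: DiscretizedMatrix, theta: float, replicates: int,
                pair_source: str | nx.Graph = "all_pairs",
                seed: int = 0, block_size: int = 1024) -> NullCensus:
    """Count, per gene pair, the replicates in which it passes the theta filter.

    Each replicate shuffles every row independently (its own RNG substream
    spawned from ``seed``, so the census is reproducible and independent of
    replicate execution order) and re-scores the pairs; a pair "appears"
    when it is classified con or re with strength strictly above theta.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    g = d.n_genes
    backbone_mode = isinstance(pair_source, nx.Graph)
    if backbone_mode:
        idx = {gid: k for k, gid in enumerate(d.gene_ids)}
        edges = [(idx[a], idx[b]) for a, b in pair_source.edges()
                 if a in idx and b in idx]
        ii = np.array([e[0] for e in edges], dtype=np.int64)
        jj = np.array([e[1] for e in edges], dtype=np.int64)
        counts = np.zeros(len(edges), dtype=np.int64)
    elif pair_source == "all_pairs":
        counts = np.zeros(g * (g - 1) // 2, dtype=np.int64)
    else:
        raise ValueError(f"unknown pair_source {pair_source!r}")

    streams = np.random.SeedSequence(seed).spawn(replicates)
    for r in range(replicates):
        rng = np.random.Generator(np.random.PCG64(streams[r]))
        shuffled = shuffle_rows(d, rng)
        if backbone_mode:
            same, opp, mixed = _edge_count_stats(shuffled.states, ii, jj)
        else:
            same, opp, mixed = pair_count_stats(shuffled.states, block_size=block_size)
        is_con, is_re = _classify_counts(same, opp, mixed, theta, d.n_samples)
        counts += (is_con | is_re)

    if backbone_mode:
        keys = [(min(d.gene_ids[a], d.gene_ids[b]), max(d.gene_ids[a], d.gene_ids[b]))
                for a, b in zip(ii, jj)]
    else:
        iu, ju = condensed_pair_indices(g)
        keys = None
    appearance: dict[tuple[str, str], int] = {}
    nz = np.flatnonzero(counts)
    for k in nz:
        if keys is not None:
            key = keys[k]
        else:
            a, b = d.gene_ids[iu[k]], d.gene_ids[ju[k]]
            key = (a, b) if a < b else (b, a)
        appearance[key] = int(counts[k])
    return NullCensus(replicates=replicates, appearance=appearance,
                      rng_seed=seed, theta=theta)


def p_value(t_appear: int, replicates: int = DEFAULT_REPLICATES) -> float:
    """(T_appear + 1) / replicates — the published rule at 1000 replicates,
    generalized to other replicate counts. Never returns 0; a pair absent
    from every replicate gets 1/replicates."""
    if not 0 <= t_appear <= replicates:
        raise ValueError(f"t_appear must be in [0, {replicates}], got {t_appear}")
    return (t_appear + 1) / replicates


def validate(candidates: list[CandidateInteraction], census: NullCensus,
             alpha: float = DEFAULT_ALPHA, strict: bool = True
             ) -> list[CandidateInteraction]:
    """Attach permutation p-values and keep the significant candidates.

    ``strict=True`` keeps p < alpha (default, matching the network
    construction rule); ``strict=False`` keeps p <= alpha.
    """
    out: list[CandidateInteraction] = []
    for c in candidates:
        pv = p_value(census.t_appear(c.gene_a, c.gene_b), census.replicates)
        keep = pv < alpha if strict else pv <= alpha
        if keep:
            out.append(CandidateInteraction(
                gene_a=c.gene_a, gene_b=c.gene_b, reg_type=c.reg_type,
                score=c.score, p_value=pv, stage="validated"))
    return out
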