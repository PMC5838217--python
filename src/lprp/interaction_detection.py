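"""Pairwise interaction scoring on the ternary state matrix.

For a gene pair the nine joint-state probabilities P(v_i, v_j) over
{-1,0,1}^2 are estimated by counting samples. A pair is *forward regulated*
(con) when concordant mass P(-1,-1)+P(1,1)+P(0,0) exceeds the discordant
mass P(-1,1)+P(1,-1)+P(0,0) and its excess over the mixed-zero mass
P(-1,0)+P(0,-1)+P(1,0)+P(0,1)+P(0,0) is strictly greater than a threshold
theta; *reverse regulated* (re) is the mirror with concordant and discordant
roles swapped. The shared P(0,0) term cancels in every difference, so both
direction margins and strengths are differences of integer sample counts
divided by N — all threshold comparisons here are therefore done on integer
counts, with the theta cutoff lifted to counts exactly (via rational
arithmetic on the float threshold), so a strict inequality can never be
flipped by float rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Iterator

import networkx as nx
import numpy as np
import pandas as pd

from .discretization import DiscretizedMatrix

STATES = (-1, 0, 1)
DEFAULT_THETA = 0.1

CON_STATES = ((-1, -1), (1, 1))
RE_STATES = ((-1, 1), (1, -1))
MIXED_ZERO_STATES = ((-1, 0), (0, -1), (1, 0), (0, 1))


@dataclass
class JointStateTable:
    """The nine joint probabilities of a gene pair's discretized states.

    Built from integer sample counts; every probability times ``n`` is an
    exact count.
    """

    p: dict[tuple[int, int], float]
    n: int

    @classmethod
    def from_counts(cls, counts: dict[tuple[int, int], int], n: int) -> "JointStateTable":
        if n <= 0:
            raise ValueError("sample count must be positive")
        total = sum(counts.values())
        if total != n:
            raise ValueError(f"joint counts sum to {total}, expected {n}")
        p = {(a, b): counts.get((a, b), 0) / n for a in STATES for b in STATES}
        return cls(p, n)

    def counts(self) -> dict[tuple[int, int], int]:
        """Recover the integer counts (exact because p = count / n)."""
        return {k: round(v * self.n) for k, v in self.p.items()}


def joint_probabilities(d: DiscretizedMatrix, i: int, j: int) -> JointStateTable:
    """Empirical joint distribution of states of genes ``i`` and ``j``."""
    if i == j:
        raise ValueError("joint probabilities require two distinct genes")
    ri, rj = d.states[i], d.states[j]
    counts = {(a, b): int(np.count_nonzero((ri == a) & (rj == b)))
              for a in STATES for b in STATES}
    return JointStateTable.from_counts(counts, d.n_samples)


def con_score(t: JointStateTable) -> tuple[float, float]:
    """Forward-regulation (direction margin, strength), as literally defined.

    direction_margin = (P(-1,-1)+P(1,1)+P(0,0)) - (P(-1,1)+P(1,-1)+P(0,0));
    strength        = (P(-1,-1)+P(1,1)+P(0,0))
                      - (P(-1,0)+P(0,-1)+P(1,0)+P(0,1)+P(0,0)).
    P(0,0) cancels algebraically in both.
    """
    p = t.p
    same = p[(-1, -1)] + p[(1, 1)] + p[(0, 0)]
    opp = p[(-1, 1)] + p[(1, -1)] + p[(0, 0)]
    mixed = p[(-1, 0)] + p[(0, -1)] + p[(1, 0)] + p[(0, 1)] + p[(0, 0)]
    return same - opp, same - mixed


def re_score(t: JointStateTable) -> tuple[float, float]:
    """Reverse-regulation (direction margin, strength): mirror of con_score
    with the anti-diagonal states {(-1,1),(1,-1)} playing the concordant role."""
    p = t.p
    same = p[(-1, -1)] + p[(1, 1)] + p[(0, 0)]
    opp = p[(-1, 1)] + p[(1, -1)] + p[(0, 0)]
    mixed = p[(-1, 0)] + p[(0, -1)] + p[(1, 0)] + p[(0, 1)] + p[(0, 0)]
    return opp - same, opp - mixed


def strength_count_cutoff(theta: float, n: int) -> int:
    """Smallest integer count difference c with c/n strictly > theta.

    Computed with exact rational arithmetic on the binary value of ``theta``
    so count-based classification agrees exactly with probability-based
    evaluation of the strict inequality strength > theta.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    tn = Fraction(theta) * n
    floor = tn.numerator // tn.denominator
    return floor + 1


def classify_pair(t: JointStateTable, theta: float = DEFAULT_THETA) -> str:
    """Classify a pair as ``"con"``, ``"re"`` or ``"none"``.

    con requires a strictly positive forward direction margin and forward
    strength strictly above theta; re is the mirror. The two direction
    margins are exact negatives, so at most one label can fire; an exact
    tie (margin 0) is ``"none"``.
    """
    c = t.counts()
    same = c[(-1, -1)] + c[(1, 1)]
    opp = c[(-1, 1)] + c[(1, -1)]
    mixed = sum(c[s] for s in MIXED_ZERO_STATES)
    cutoff = strength_count_cutoff(theta, t.n)
    if same > opp and same - mixed >= cutoff:
        return "con"
    if opp > same and opp - mixed >= cutoff:
        return "re"
    return "none"


@dataclass
class CandidateInteraction:
    """An unordered gene pair with its regulation label and pipeline state.

    ``gene_a < gene_b`` lexicographically (canonical form). ``score`` is the
    winning strength; ``p_value`` stays ``None`` until permutation
    validation; ``stage`` tracks provenance through the pipeline.
    """

    gene_a: str
    gene_b: str
    reg_type: str
    score: float
    p_value: float | None = None
    stage: str = "candidate"

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-interaction {self.gene_a!r}")
        if self.gene_a > self.gene_b:
            self.gene_a, self.gene_b = self.gene_b, self.gene_a
        if self.reg_type not in ("con", "re"):
            raise ValueError(f"reg_type must be 'con' or 're', got {self.reg_type!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


# ---------------------------------------------------------------------------
# Vectorized pair statistics
# ---------------------------------------------------------------------------

def _indicators(states: np.ndarray) -> dict[int, np.ndarray]:
    return {s: (states == s).astype(np.int64) for s in STATES}


def pair_count_stats(states: np.ndarray, block_size: int = 1024
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integer count statistics for every unordered gene pair i < j.

    Returns condensed (upper-triangle, row-major) arrays ``(same, opp,
    mixed)`` where same = #samples both genes share a nonzero state, opp =
    #samples they hold opposite nonzero states and mixed = #samples exactly
    one of the two is zero. Works block-wise over gene rows so peak memory
    scales with ``block_size**2``, not with the total pair count.
    """
    g = states.shape[0]
    n_pairs = g * (g - 1) // 2
    same = np.empty(n_pairs, dtype=np.int64)
    opp = np.empty(n_pairs, dtype=np.int64)
    mixed = np.empty(n_pairs, dtype=np.int64)

    ind = _indicators(states)
    offsets = _condensed_offsets(g)
    for bi in range(0, g, block_size):
        ei = min(bi + block_size, g)
        for bj in range(bi, g, block_size):
            ej = min(bj + block_size, g)
            s_blk = (ind[-1][bi:ei] @ ind[-1][bj:ej].T
                     + ind[1][bi:ei] @ ind[1][bj:ej].T)
            o_blk = (ind[-1][bi:ei] @ ind[1][bj:ej].T
                     + ind[1][bi:ei] @ ind[-1][bj:ej].T)
            m_blk = (ind[-1][bi:ei] @ ind[0][bj:ej].T
                     + ind[0][bi:ei] @ ind[-1][bj:ej].T
                     + ind[1][bi:ei] @ ind[0][bj:ej].T
                     + ind[0][bi:ei] @ ind[1][bj:ej].T)
            for li, i in enumerate(range(bi, ei)):
                j_start = max(bj, i + 1)
                if j_start >= ej:
                    continue
                dest = offsets[i] + (j_start - i - 1)
                lj = j_start - bj
                w = ej - j_start
                same[dest:dest + w] = s_blk[li, lj:]
                opp[dest:dest + w] = o_blk[li, lj:]
                mixed[dest:dest + w] = m_blk[li, lj:]
    return same, opp, mixed


def _condensed_offsets(g: int) -> np.ndarray:
    """offsets[i] = condensed index of pair (i, i+1)."""
    sizes = np.arange(g - 1, -1, -1, dtype=np.int64)
    return np.concatenate(([0], np.cumsum(sizes)[:-1]))


def condensed_pair_indices(g: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/col gene indices for each condensed pair position."""
    iu, ju = np.triu_indices(g, k=1)
    return iu, ju


def _classify_counts(same: np.ndarray, opp: np.ndarray, mixed: np.ndarray,
                     theta: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    cutoff = strength_count_cutoff(theta, n)
    is_con = (same > opp) & (same - mixed >= cutoff)
    is_re = (opp > same) & (opp - mixed >= cutoff)
    return is_con, is_re


def detect_interactions(d: DiscretizedMatrix, theta: float = DEFAULT_THETA,
                        pair_source: str | nx.Graph = "all_pairs",
                        block_size: int = 1024) -> list[CandidateInteraction]:
    """Score gene pairs and return con/re candidates in canonical order.

    ``pair_source="all_pairs"`` scans every unordered pair; passing a
    backbone graph restricts scoring to backbone edges whose endpoints both
    occur in ``d`` (an error if no backbone gene is present).
    Output is sorted lexicographically by (gene_a, gene_b).
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    n = d.n_samples
    out: list[CandidateInteraction] = []
    if isinstance(pair_source, nx.Graph):
        idx = {g: k for k, g in enumerate(d.gene_ids)}
        pairs = [(idx[a], idx[b]) for a, b in pair_source.edges()
                 if a in idx and b in idx]
        if not pairs and pair_source.number_of_edges() > 0:
            raise ValueError("backbone shares no scorable gene pair with the matrix")
        if not pairs:
            return []
        ii = np.array([p[0] for p in pairs])
        jj = np.array([p[1] for p in pairs])
        same, opp, mixed = _edge_count_stats(d.states, ii, jj)
        src_i, src_j = ii, jj
    elif pair_source == "all_pairs":
        same, opp, mixed = pair_count_stats(d.states, block_size=block_size)
        src_i, src_j = condensed_pair_indices(d.n_genes)
    else:
        raise ValueError(f"unknown pair_source {pair_source!r}")

    is_con, is_re = _classify_counts(same, opp, mixed, theta, n)
    for k in np.flatnonzero(is_con | is_re):
        con = bool(is_con[k])
        strength = (same[k] if con else opp[k]) - mixed[k]
        out.append(CandidateInteraction(
            gene_a=d.gene_ids[src_i[k]], gene_b=d.gene_ids[src_j[k]],
            reg_type="con" if con else "re", score=float(strength / n)))
    out.sort(key=lambda c: c.pair)
    return out


def _edge_count_stats(states: np.ndarray, ii: np.ndarray, jj: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a, b = states[ii], states[jj]
    nz_a, nz_b = a != 0, b != 0
    same = np.count_nonzero(nz_a & (a == b), axis=1)
    opp = np.count_nonzero(nz_a & nz_b & (a == -b), axis=1)
    mixed = np.count_nonzero(nz_a ^ nz_b, axis=1)
    return same.astype(np.int64), opp.astype(np.int64), mixed.astype(np.int64)


def theta_sweep(d: DiscretizedMatrix, grid: Iterable[float],
                block_size: int = 1024) -> pd.DataFrame:
    """Census of detections over a theta grid (Fig.-2-style table).

    Returns a DataFrame with columns ``theta, n_interactions, n_genes,
    n_con, n_re`` where n_genes counts the genes touched by at least one
    detected interaction. Counts are non-increasing in theta.
    """
    grid = list(grid)
    if grid != sorted(grid):
        raise ValueError("theta grid must be sorted ascending")
    same, opp, mixed = pair_count_stats(d.states, block_size=block_size)
    iu, ju = condensed_pair_indices(d.n_genes)
    rows = []
    for theta in grid:
        is_con, is_re = _classify_counts(same, opp, mixed, theta, d.n_samples)
        hit = is_con | is_re
        touched = np.unique(np.concatenate([iu[hit], ju[hit]])).size if hit.any() else 0
        rows.append({"theta": theta,
                     "n_interactions": int(hit.sum()),
                     "n_genes": int(touched),
                     "n_con": int(is_con.sum()),
                     "n_re": int(is_re.sum())})
    return pd.DataFrame(rows)
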