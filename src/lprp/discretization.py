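"""Ternary discretization of expression matrices.

Each gene row is mapped to states {-1, 0, 1} relative to its own mean and
standard deviation: values inside the band ``avg_i +/- gamma * sd_i`` become
0 (band boundaries inclusive), values below become -1 and values above +1.
The band half-width ``gamma`` (in sd units) defaults to 0.45.

A diagnostic "gamma scan" compares the symbol-frequency distribution of the
discretized matrix against that of a random uniform ternary matrix of the
same shape, the rationale being that a well-chosen band makes the per-gene
-1/0/1 count distribution resemble the maximally uninformative one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression_io import ExpressionMatrix

DEFAULT_GAMMA = 0.45
STATES = (-1, 0, 1)


@dataclass
class DiscretizationParams:
    """Band half-width ``gamma`` in [0, 1] and the sd estimator convention.

    ``sd_mode="sample"`` uses the n-1 denominator, ``"population"`` uses n.
    """

    gamma: float = DEFAULT_GAMMA
    sd_mode: str = "sample"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.sd_mode not in ("sample", "population"):
            raise ValueError(f"sd_mode must be 'sample' or 'population', got {self.sd_mode!r}")


@dataclass
class DiscretizedMatrix:
    """Ternary state matrix with the same shape and labels as its source."""

    gene_ids: list[str]
    sample_ids: list[str]
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("state matrix shape does not match gene/sample IDs")
        if not np.isin(self.states, STATES).all():
            raise ValueError("states must all be in {-1, 0, 1}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def discretize(m: ExpressionMatrix, p: DiscretizationParams | None = None) -> DiscretizedMatrix:
    """Discretize each gene row around its own mean with a gamma*sd band.

    For a constant row sd is 0, the band degenerates to the mean and every
    entry maps to 0. With a single sample the sample sd is undefined and is
    treated as 0 for the same reason.
    """
    p = p or DiscretizationParams()
    v = m.values
    avg = v.mean(axis=1, keepdims=True)
    if p.sd_mode == "sample" and m.n_samples < 2:
        sd = np.zeros_like(avg)
    else:
        sd = v.std(axis=1, ddof=1 if p.sd_mode == "sample" else 0, keepdims=True)
    lo = avg - p.gamma * sd
    hi = avg + p.gamma * sd
    states = np.zeros(v.shape, dtype=np.int8)
    states[v < lo] = -1
    states[v > hi] = 1
    return DiscretizedMatrix(list(m.gene_ids), list(m.sample_ids), states)


# ---------------------------------------------------------------------------
# Symbol-frequency diagnostics
# ---------------------------------------------------------------------------

@dataclass
class SymbolFrequencyProfile:
    """Per-gene counts of -1/0/1 plus the aggregated count histogram.

    ``counts`` has one row per gene and columns ordered (-1, 0, 1); each row
    sums to the sample count. ``histogram()`` gives, for each symbol, how
    many genes carry each possible per-gene count of that symbol — the
    frequency-distribution view used to judge a discretization band.
    """

    counts: np.ndarray
    n_samples: int
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 3:
            raise ValueError("counts must be (n_genes, 3)")
        if not (self.counts.sum(axis=1) == self.n_samples).all():
            raise ValueError("per-gene symbol counts must sum to the sample count")

    def histogram(self) -> np.ndarray:
        """(3, n_samples+1) array: row s, column c = #genes with c copies of symbol s."""
        out = np.zeros((3, self.n_samples + 1), dtype=np.int64)
        for s in range(3):
            out[s] = np.bincount(self.counts[:, s], minlength=self.n_samples + 1)
        return out


def symbol_frequency_profile(d: DiscretizedMatrix) -> SymbolFrequencyProfile:
    counts = np.stack([(d.states == s).sum(axis=1) for s in STATES], axis=1)
    return SymbolFrequencyProfile(counts, d.n_samples, list(d.gene_ids))


def random_reference_profile(n_genes: int, n_samples: int,
                             rng: np.random.Generator) -> SymbolFrequencyProfile:
    """Profile of an i.i.d. uniform ternary matrix of the given shape."""
    states = rng.integers(-1, 2, size=(n_genes, n_samples)).astype(np.int8)
    d = DiscretizedMatrix([f"R{i}" for i in range(n_genes)],
                          [f"S{j}" for j in range(n_samples)], states)
    return symbol_frequency_profile(d)


def profile_divergence(a: SymbolFrequencyProfile, b: SymbolFrequencyProfile) -> float:
    """Mean total-variation distance between the two aggregated histograms.

    Each symbol's per-gene count histogram is normalized to a distribution;
    the TV distances for -1, 0 and 1 are averaged. Bounded in [0, 1].
    """
    if a.n_samples != b.n_samples:
        raise ValueError("profiles must share the sample count")
    ha = a.histogram().astype(float)
    hb = b.histogram().astype(float)
    ha /= ha.sum(axis=1, keepdims=True)
    hb /= hb.sum(axis=1, keepdims=True)
    return float(0.5 * np.abs(ha - hb).sum(axis=1).mean())


@dataclass
class GammaScanResult:
    gammas: list[float]
    divergences: list[float]
    recommended: float


def gamma_scan(m: ExpressionMatrix, grid: list[float],
               reference: SymbolFrequencyProfile,
               sd_mode: str = "sample") -> GammaScanResult:
    """Score each candidate band width against a reference symbol profile.

    Returns the divergence per gamma and the gamma minimizing it (first
    minimum on ties). This is a diagnostic: the pipeline default stays 0.45
    regardless of the recommendation.
    """
    if not grid:
        raise ValueError("gamma grid must be non-empty")
    divs = []
    for g in grid:
        d = discretize(m, DiscretizationParams(gamma=g, sd_mode=sd_mode))
        divs.append(profile_divergence(symbol_frequency_profile(d), reference))
    best = int(np.argmin(divs))
    return GammaScanResult(list(grid), divs, float(grid[best]))


def write_discretized(d: DiscretizedMatrix, path, id_header: str = "gene_id") -> None:
    """Write the state matrix as TSV of -1/0/1 with the input's header layout."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write(id_header + "\t" + "\t".join(d.sample_ids) + "\n")
        for gid, row in zip(d.gene_ids, d.states):
            fh.write(gid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_discretized(path) -> DiscretizedMatrix:
    from .expression_io import read_expression_matrix

    m = read_expression_matrix(path)
    states = m.values.astype(np.int8)
    if not np.array_equal(states, m.values):
        raise ValueError(f"{path}: non-integer entries in discretized matrix")
    return DiscretizedMatrix(m.gene_ids, m.sample_ids, states)
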