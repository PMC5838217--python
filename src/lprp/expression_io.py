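"""Reading and writing expression matrices, backbone networks and interaction lists.

Expression matrices are plain tab-separated text: a header row of sample IDs
and one row per gene, first column the gene ID. Backbone interaction networks
("KP"-style protein-interaction graphs) are accepted either as two-column edge
lists or as three-column SIF (``node1 <relation> node2``); the relation token
is ignored on read because the backbone is treated as an untyped undirected
graph. Gene IDs are opaque case-sensitive strings.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates a structural invariant (e.g. duplicate gene IDs)."""


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample expression table.

    Rows are genes, columns are samples. Values are dimensionless normalized
    expression (e.g. normalized RNA-seq counts); they must be finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ValidationError(f"duplicate gene IDs: {sorted(dupes)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicate sample IDs: {sorted(dupes)}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must all be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in items:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    First row is the sample header (its first field, the gene-ID column
    header, is arbitrary and ignored); each following row is a gene ID plus
    one numeric value per sample. Duplicate gene IDs are an error, never
    silently merged.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty expression file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise ParseError(f"{path}: line 1: header has no sample columns")
    n_cols = len(sample_ids)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_cols + 1:
            raise ParseError(
                f"{path}: line {lineno}: expected {n_cols + 1} fields, got {len(fields)}"
            )
        gene_ids.append(fields[0])
        try:
            rows.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric value ({exc})") from None
    try:
        return ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=float))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_expression_matrix(m: ExpressionMatrix, path: str | Path,
                            id_header: str = "gene_id", fmt: str = "%.17g") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(id_header + "\t" + "\t".join(m.sample_ids) + "\n")
        for gid, row in zip(m.gene_ids, m.values):
            fh.write(gid + "\t" + "\t".join(fmt % v for v in row) + "\n")


def filter_unexpressed(m: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes whose expression is zero across all samples.

    Row order is preserved. Raises :class:`ValidationError` if the filter
    would remove every gene.
    """
    keep = np.any(m.values != 0, axis=1)
    if not keep.any():
        raise ValidationError("all genes are zero across all samples")
    if keep.all():
        return m
    gene_ids = [g for g, k in zip(m.gene_ids, keep) if k]
    return ExpressionMatrix(gene_ids, list(m.sample_ids), m.values[keep])


# ---------------------------------------------------------------------------
# Backbone networks
# ---------------------------------------------------------------------------

def read_backbone(path: str | Path) -> nx.Graph:
    """Read an undirected backbone network from an edge list or SIF file.

    The dialect (2 fields = edge list, 3 fields = SIF) is inferred from the
    first data line and enforced for the rest of the file. Self-loops are
    dropped and duplicate edges collapsed regardless of orientation, so the
    result has no isolated nodes by construction.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    data = [(i + 1, ln.split("\t") if "\t" in ln else ln.split())
            for i, ln in enumerate(lines) if ln.strip()]
    if not data:
        raise ParseError(f"{path}: empty backbone file")
    width = len(data[0][1])
    if width not in (2, 3):
        raise ParseError(f"{path}: line {data[0][0]}: expected 2 (edge list) or 3 (SIF) fields")
    g: nx.Graph = nx.Graph()
    for lineno, fields in data:
        if len(fields) != width:
            raise ParseError(f"{path}: line {lineno}: expected {width} fields, got {len(fields)}")
        a, b = (fields[0], fields[1]) if width == 2 else (fields[0], fields[2])
        if a == b:
            continue
        g.add_edge(a, b)
    return g


def write_backbone(g: nx.Graph, path: str | Path, sif_relation: str = "pp") -> None:
    """Write an undirected graph as SIF (one ``a pp b`` line per edge)."""
    path = Path(path)
    with path.open("w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{a}\t{sif_relation}\t{b}\n")


# ---------------------------------------------------------------------------
# Gene lists and candidate-interaction tables
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-ID-per-line gene list, preserving order, dropping blanks."""
    with Path(path).open() as fh:
        return [ln.strip() for ln in fh if ln.strip()]


CANDIDATE_COLUMNS = ("gene_a", "gene_b", "type", "score", "p_value", "stage")


def write_candidates(candidates: Iterable, path: str | Path) -> None:
    """Write candidate interactions as TSV (columns: gene_a, gene_b, type,
    score, p_value, stage); unset p-values are written as ``NA``."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for c in candidates:
            pv = "NA" if c.p_value is None else "%.17g" % c.p_value
            fh.write(f"{c.gene_a}\t{c.gene_b}\t{c.reg_type}\t{'%.17g' % c.score}\t{pv}\t{c.stage}\n")


def read_candidates(path: str | Path) -> list:
    from .interaction_detection import CandidateInteraction

    path = Path(path)
    out = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != CANDIDATE_COLUMNS:
            raise ParseError(f"{path}: line 1: unexpected candidate-table header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                raise ParseError(f"{path}: line {lineno}: expected 6 fields, got {len(fields)}")
            a, b, typ, score, pv, stage = fields
            out.append(CandidateInteraction(
                gene_a=a, gene_b=b, reg_type=typ, score=float(score),
                p_value=None if pv == "NA" else float(pv), stage=stage))
    return out


# ---------------------------------------------------------------------------
# Network output
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("sif", "graphml", "edge_tsv")


def write_network(g, path: str | Path, format: str = "sif") -> None:
    """Write a GGI network (or bare graph) in one of ``sif``, ``graphml``,
    ``edge_tsv``.

    SIF and edge_tsv carry the edge set only and round-trip through
    :func:`read_backbone`; GraphML additionally carries per-edge attributes
    ``type``, ``score``, ``p_value`` and ``stage``.
    """
    if isinstance(g, nx.Graph):
        graph = g
    elif hasattr(g, "graph") and isinstance(g.graph, nx.Graph):
        graph = g.graph
    else:
        raise TypeError("write_network expects a GGINetwork or networkx Graph")
    path = Path(path)
    if format == "sif":
        write_backbone(graph, path)
    elif format == "edge_tsv":
        with path.open("w") as fh:
            for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
                fh.write(f"{a}\t{b}\n")
    elif format == "graphml":
        out = nx.Graph()
        out.add_nodes_from(sorted(graph.nodes()))
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            d = graph.edges[a, b]
            out.add_edge(a, b,
                         type=str(d.get("type", "")),
                         score=float(d.get("score", 0.0)),
                         p_value=float(d.get("p_value") if d.get("p_value") is not None else -1.0),
                         stage=str(d.get("stage", "")))
        nx.write_graphml(out, path)
    else:
        raise ValueError(f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}")


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(Path(path))


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
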