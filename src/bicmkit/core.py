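"""Biadjacency data model, I/O and elementary bipartite topology.

A binary bipartite network linking two node layers — conventionally called
"rows"/"countries" (layer 0) and "columns"/"products" (layer 1) — is stored
as a labeled 0/1 biadjacency matrix ``M`` of shape ``(C, P)``.  Intra-layer
links do not exist by construction, so the rectangular matrix is a complete
description of the network.

The elementary quantities defined here are:

* number of links ``L = sum(M)``,
* connectance ``L / (C * P)``,
* rectangularity ``R = |P - C| / (P + C)`` — a sign-free measure of the
  asymmetry between the layer cardinalities, in ``[0, 1)``,
* diversification ``d_c`` (row degrees) and ubiquity ``u_p`` (column
  degrees), and their means ``L / C`` and ``L / P``,
* the weighted monopartite projections ``M @ M.T`` (rows) and ``M.T @ M``
  (columns), whose off-diagonal entries count shared neighbors and whose
  diagonal is the degree sequence, together with the binary projections
  obtained by thresholding the weights and zeroing the diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "BipartiteGraph",
    "GraphSummary",
    "Projection",
    "ParseError",
    "load_biadjacency",
    "summarize",
    "project",
    "rectangularity",
]

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted as a bipartite graph."""


@dataclass(frozen=True)
class BipartiteGraph:
    """A labeled binary biadjacency matrix.

    Parameters
    ----------
    row_labels, col_labels
        Unique identifiers of the two layers, in internal storage order.
    matrix
        Dense 0/1 array of shape ``(len(row_labels), len(col_labels))``;
        ``matrix[c, p] == 1`` iff row node *c* links column node *p*.
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2:
            raise ValueError("biadjacency matrix must be 2-dimensional")
        if m.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError(
                f"matrix shape {m.shape} does not match "
                f"{len(self.row_labels)} row / {len(self.col_labels)} column labels"
            )
        if m.shape[0] < 1 or m.shape[1] < 1:
            raise ValueError("both layers must contain at least one node")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("row labels are not unique")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("column labels are not unique")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("biadjacency entries must be 0 or 1")
        object.__setattr__(self, "matrix", m.astype(np.int8, copy=False))
        self.matrix.setflags(write=False)

    # -- convenience views -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_links(self) -> int:
        return int(self.matrix.sum())

    @property
    def row_degrees(self) -> np.ndarray:
        """Diversification ``d_c``: number of column nodes each row links."""
        return self.matrix.sum(axis=1)

    @property
    def col_degrees(self) -> np.ndarray:
        """Ubiquity ``u_p``: number of row nodes each column links."""
        return self.matrix.sum(axis=0)

    def row_index(self, labels: Sequence[str]) -> np.ndarray:
        return _label_index(self.row_labels, labels, "row")

    def col_index(self, labels: Sequence[str]) -> np.ndarray:
        return _label_index(self.col_labels, labels, "column")

    @classmethod
    def from_matrix(
        cls,
        matrix: np.ndarray,
        row_labels: Sequence[str] | None = None,
        col_labels: Sequence[str] | None = None,
    ) -> "BipartiteGraph":
        m = np.asarray(matrix)
        rows = tuple(map(str, row_labels)) if row_labels is not None else tuple(
            f"r{i}" for i in range(m.shape[0])
        )
        cols = tuple(map(str, col_labels)) if col_labels is not None else tuple(
            f"c{j}" for j in range(m.shape[1])
        )
        return cls(rows, cols, m)


def _label_index(
    universe: tuple[str, ...], labels: Sequence[str], layer: str
) -> np.ndarray:
    lookup = {lab: i for i, lab in enumerate(universe)}
    try:
        return np.array([lookup[str(lab)] for lab in labels], dtype=np.intp)
    except KeyError as exc:
        raise KeyError(f"unknown {layer} label: {exc.args[0]!r}") from None


@dataclass(frozen=True)
class GraphSummary:
    """Elementary topological summary of a bipartite graph."""

    n_rows: int
    n_cols: int
    n_links: int
    connectance: float
    rectangularity: float
    diversification: np.ndarray
    ubiquity: np.ndarray
    mean_degree_rows: float
    mean_degree_cols: float
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "n_links": self.n_links,
            "connectance": self.connectance,
            "rectangularity": self.rectangularity,
            "diversification": dict(
                zip(self.row_labels, map(int, self.diversification))
            ),
            "ubiquity": dict(zip(self.col_labels, map(int, self.ubiquity))),
            "mean_degree_rows": self.mean_degree_rows,
            "mean_degree_cols": self.mean_degree_cols,
        }


@dataclass(frozen=True)
class Projection:
    """Monopartite projection of one layer of a bipartite graph.

    ``weights[i, j]`` (``i != j``) counts the neighbors shared by nodes *i*
    and *j* of the projected layer; the diagonal carries the layer's degree
    sequence.  ``binary`` is the thresholded adjacency (1 iff at least one
    shared neighbor) with a zero diagonal.
    """

    labels: tuple[str, ...]
    weights: np.ndarray
    binary: np.ndarray

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "weights": self.weights.tolist(),
            "binary": self.binary.tolist(),
        }


def rectangularity(n_rows: int, n_cols: int) -> float:
    """Layer-size asymmetry ``|P - C| / (P + C)``, in ``[0, 1)``.

    Symmetric in the two layers: the sign of ``P - C`` would depend on the
    arbitrary ordering of the layers, so only the magnitude is kept.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("layer sizes must be positive")
    return abs(n_cols - n_rows) / (n_cols + n_rows)


def summarize(g: BipartiteGraph) -> GraphSummary:
    """Compute links, connectance, rectangularity and degree sequences."""
    L = g.n_links
    C, P = g.n_rows, g.n_cols
    return GraphSummary(
        n_rows=C,
        n_cols=P,
        n_links=L,
        connectance=L / (C * P),
        rectangularity=rectangularity(C, P),
        diversification=g.row_degrees.astype(np.int64),
        ubiquity=g.col_degrees.astype(np.int64),
        mean_degree_rows=L / C,
        mean_degree_cols=L / P,
        row_labels=g.row_labels,
        col_labels=g.col_labels,
    )


def project(g: BipartiteGraph, layer: Literal["rows", "cols"]) -> Projection:
    """Monopartite projection ``M @ M.T`` (rows) or ``M.T @ M`` (cols)."""
    m = g.matrix.astype(np.int64)
    if layer == "rows":
        weights = m @ m.T
        labels = g.row_labels
    elif layer == "cols":
        weights = m.T @ m
        labels = g.col_labels
    else:
        raise ValueError(f"layer must be 'rows' or 'cols', got {layer!r}")
    binary = (weights >= 1).astype(np.int8)
    np.fill_diagonal(binary, 0)
    return Projection(labels=labels, weights=weights, binary=binary)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_biadjacency(
    path: str | Path,
    fmt: Literal["dense", "edgelist", "sparse-coo"] = "dense",
    *,
    row_labels_path: str | Path | None = None,
    col_labels_path: str | Path | None = None,
) -> BipartiteGraph:
    """Read a biadjacency matrix from disk.

    Formats
    -------
    dense
        TSV/CSV: first row holds column labels, first column row labels,
        cells are 0/1.  Any strictly positive cell is coerced to 1 with a
        warning (inputs are expected to be pre-thresholded).
    edgelist
        Two whitespace-separated label columns ``row_label col_label``;
        ``#`` starts a comment; duplicate edges collapse to a single link.
    sparse-coo
        Matrix-Market-style coordinate triples ``i j [value]`` (1-based)
        preceded by a ``rows cols [nnz]`` size line; ``%``/``#`` comments
        allowed.  Node labels come from the optional side files
        ``row_labels_path``/``col_labels_path`` (one label per line) and
        default to ``r1..rC`` / ``c1..cP``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    if path.stat().st_size == 0:
        raise ParseError(f"empty input file: {path}")
    if fmt == "dense":
        return _load_dense(path)
    if fmt == "edgelist":
        return _load_edgelist(path)
    if fmt == "sparse-coo":
        return _load_sparse_coo(path, row_labels_path, col_labels_path)
    raise ValueError(f"unknown format {fmt!r}")


def _split_table_line(line: str) -> list[str]:
    sep = "\t" if "\t" in line else ("," if "," in line else None)
    return [f.strip() for f in line.rstrip("\n").split(sep)]


def _load_dense(path: Path) -> BipartiteGraph:
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ParseError(f"{path}: dense file needs a header and at least one row")
    header = _split_table_line(lines[0])
    col_labels = header[1:] if header[0] == "" or len(header) > 1 else header
    # header may or may not carry a stub cell above the row-label column
    rows: list[str] = []
    values: list[list[int]] = []
    coerced = False
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = _split_table_line(ln)
        if len(fields) != len(col_labels) + 1:
            # header had no stub cell for the row-label column
            if lineno == 2 and len(fields) == len(header) + 1:
                col_labels = header
            if len(fields) != len(col_labels) + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {len(col_labels) + 1} fields, "
                    f"got {len(fields)}"
                )
        rows.append(fields[0])
        row_vals = []
        for j, cell in enumerate(fields[1:], start=1):
            try:
                v = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric cell {cell!r} in column {j}"
                ) from None
            if v < 0:
                raise ParseError(f"{path}:{lineno}: negative cell value {v}")
            if v not in (0.0, 1.0):
                coerced = True
            row_vals.append(1 if v > 0 else 0)
        values.append(row_vals)
    if coerced:
        logger.warning(
            "%s: non-binary cells found; strictly positive values coerced to 1",
            path,
        )
    return BipartiteGraph(tuple(rows), tuple(col_labels), np.array(values))


def _load_edgelist(path: Path) -> BipartiteGraph:
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            stripped = ln.split("#", 1)[0].strip()
            if not stripped:
                continue
            fields = stripped.split()
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected two label columns, got "
                    f"{len(fields)} fields"
                )
            edges.append((fields[0], fields[1]))
    if not edges:
        raise ParseError(f"{path}: no edges found")
    row_labels = list(dict.fromkeys(r for r, _ in edges))
    col_labels = list(dict.fromkeys(c for _, c in edges))
    ridx = {lab: i for i, lab in enumerate(row_labels)}
    cidx = {lab: j for j, lab in enumerate(col_labels)}
    m = np.zeros((len(row_labels), len(col_labels)), dtype=np.int8)
    for r, c in edges:
        m[ridx[r], cidx[c]] = 1  # duplicates collapse
    return BipartiteGraph(tuple(row_labels), tuple(col_labels), m)


def _read_label_file(path: str | Path | None, prefix: str, n: int) -> tuple[str, ...]:
    if path is None:
        return tuple(f"{prefix}{i + 1}" for i in range(n))
    with open(path) as fh:
        labels = [ln.strip() for ln in fh if ln.strip()]
    if len(labels) != n:
        raise ParseError(
            f"{path}: {len(labels)} labels for a layer of {n} nodes"
        )
    return tuple(labels)


def _load_sparse_coo(
    path: Path,
    row_labels_path: str | Path | None,
    col_labels_path: str | Path | None,
) -> BipartiteGraph:
    entries: list[list[float]] = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            stripped = ln.strip()
            if not stripped or stripped.startswith(("%", "#")):
                continue
            fields = stripped.split()
            try:
                entries.append([float(f) for f in fields])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric field in coordinate line"
                ) from None
    if not entries:
        raise ParseError(f"{path}: no coordinate data found")
    size_line, coords = entries[0], entries[1:]
    if len(size_line) < 2:
        raise ParseError(f"{path}: size line must give 'rows cols [nnz]'")
    C, P = int(size_line[0]), int(size_line[1])
    m = np.zeros((C, P), dtype=np.int8)
    for k, triple in enumerate(coords):
        if len(triple) < 2:
            raise ParseError(f"{path}: coordinate line {k + 2} too short")
        i, j = int(triple[0]) - 1, int(triple[1]) - 1
        if not (0 <= i < C and 0 <= j < P):
            raise ParseError(
                f"{path}: coordinate ({i + 1}, {j + 1}) outside {C}x{P} matrix"
            )
        value = triple[2] if len(triple) > 2 else 1.0
        if value > 0:
            m[i, j] = 1
    return BipartiteGraph(
        _read_label_file(row_labels_path, "r", C),
        _read_label_file(col_labels_path, "c", P),
        m,
    )
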