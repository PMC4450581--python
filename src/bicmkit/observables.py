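"""Structural observables of a single binary bipartite network.

This module implements the bespoke bipartite statistics that the null
models in :mod:`bicmkit.models` are later asked to reproduce:

* **ANPU / ANCD** — the average nearest-neighbor degrees across layers.
  For a row node *c* with diversification ``d_c``, the average nearest
  products ubiquity is ``anpu_c = (1/d_c) * sum_p m_cp u_p``; symmetrically
  the average nearest countries diversification of column node *p* is
  ``ancd_p = (1/u_p) * sum_c m_cp d_c``.  Scattering these against the
  degree sequences reveals (dis)assortative mixing.  A row node's ANPU counts its
  average number of competitors per neighbor, so the mean ANPU lies in
  ``[0, C]``; dividing by the number of rows gives a normalized
  integration ("globalization") index in ``[0, 1]``.  Symmetrically the
  mean ANCD over the number of columns gives a homogeneity index.

* **Vn / Λn motifs** — co-occurrence counts.  A V-motif is a pair of row
  nodes sharing a column neighbor; ``N_V = sum_p binom(u_p, 2)``.  The
  Λ-motif is the mirror image over columns: ``N_Λ = sum_c binom(d_c, 2)``.
  Order-*n* generalizations count *n*-tuples, and restricting the tuple to
  a chosen subset of nodes yields subset-specific motifs (the degree is
  then computed only over the subset).  Order 1 gives the number of links
  for both families.

* **Newman's assortativity coefficient** *r* — the Pearson correlation,
  across links, between the degrees of the two endpoints.  In a bipartite
  graph each link has exactly one endpoint per layer, and subtracting 1
  from either degree ("remaining degree") shifts a variable by a constant,
  so the raw-degree and remaining-degree readings coincide.

* **NODF nestedness** — paired-overlap nestedness with a decreasing-fill
  condition, in ``[0, 100]``, computed over row pairs, column pairs and
  their pooled combination.  It is invariant under row/column permutations.

* **Fitness–complexity** — the coupled nonlinear iteration ranking rows by
  the quality of their neighborhoods and columns inversely by the weakness
  of their users, normalized to unit mean each step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import comb

from bicmkit.core import BipartiteGraph

__all__ = [
    "AssortativityProfile",
    "MotifSpec",
    "FitnessComplexityResult",
    "NestednessResult",
    "assortativity_profile",
    "count_motifs",
    "assortativity_coefficient",
    "nodf",
    "fitness_complexity",
    "rank_by_fitness",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Assortativity (ANPU / ANCD)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssortativityProfile:
    """Per-node average nearest-neighbor degrees and their layer means.

    ``anpu``/``ancd`` hold NaN for zero-degree nodes (the average over an
    empty neighborhood is undefined); such nodes are excluded from the
    means and confidence intervals.
    """

    anpu: np.ndarray
    ancd: np.ndarray
    mean_anpu: float
    mean_ancd: float
    ci95_anpu: tuple[float, float]
    ci95_ancd: tuple[float, float]
    globalization_index: float
    homogeneity_index: float
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "anpu": dict(zip(self.row_labels, self.anpu.tolist())),
            "ancd": dict(zip(self.col_labels, self.ancd.tolist())),
            "mean_anpu": self.mean_anpu,
            "mean_ancd": self.mean_ancd,
            "ci95_anpu": list(self.ci95_anpu),
            "ci95_ancd": list(self.ci95_ancd),
            "globalization_index": self.globalization_index,
            "homogeneity_index": self.homogeneity_index,
        }


def _mean_ci95(values: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Mean and normal-approximation 95% CI over the defined entries."""
    vals = values[~np.isnan(values)]
    if vals.size == 0:
        raise ValueError("all nodes of the layer have degree zero; mean undefined")
    mean = float(vals.mean())
    half = 1.96 * float(vals.std(ddof=1)) / math.sqrt(vals.size) if vals.size > 1 else 0.0
    return mean, (mean - half, mean + half)


def assortativity_profile(g: BipartiteGraph) -> AssortativityProfile:
    """ANPU/ANCD per node, layer means with 95% CIs, and the derived indices."""
    m = g.matrix.astype(float)
    d = g.row_degrees.astype(float)
    u = g.col_degrees.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        anpu = np.where(d > 0, (m @ u) / d, np.nan)
        ancd = np.where(u > 0, (m.T @ d) / u, np.nan)
    n_iso = int((d == 0).sum() + (u == 0).sum())
    if n_iso:
        logger.info("%d zero-degree node(s) excluded from ANPU/ANCD means", n_iso)
    mean_anpu, ci_anpu = _mean_ci95(anpu)
    mean_ancd, ci_ancd = _mean_ci95(ancd)
    return AssortativityProfile(
        anpu=anpu,
        ancd=ancd,
        mean_anpu=mean_anpu,
        mean_ancd=mean_ancd,
        ci95_anpu=ci_anpu,
        ci95_ancd=ci_ancd,
        globalization_index=mean_anpu / g.n_rows,
        homogeneity_index=mean_ancd / g.n_cols,
        row_labels=g.row_labels,
        col_labels=g.col_labels,
    )


# ---------------------------------------------------------------------------
# Motifs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifSpec:
    """Specification of one motif family: V (row tuples) or Lambda (column
    tuples), tuple size ``order``, optionally restricted to ``subset`` —
    labels of the *tupled* layer (rows for V, columns for Lambda)."""

    family: Literal["V", "Lambda"]
    order: int = 2
    subset: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.family not in ("V", "Lambda"):
            raise ValueError(f"motif family must be 'V' or 'Lambda', got {self.family!r}")
        if self.order < 1:
            raise ValueError(f"motif order must be >= 1, got {self.order}")
        if self.subset is not None:
            object.__setattr__(self, "subset", tuple(map(str, self.subset)))

    @property
    def name(self) -> str:
        base = f"{self.family}{self.order}"
        return base if self.subset is None else f"{base}[{','.join(self.subset)}]"


def restricted_degrees(g: BipartiteGraph, spec: MotifSpec) -> np.ndarray:
    """Degree sequence of the *opposite* layer, restricted to the subset.

    For a V spec this is the ubiquity of every column counted over the
    subset rows only; for Lambda, the diversification of every row over the
    subset columns.  Raises ``KeyError`` on unknown subset labels.
    """
    if spec.family == "V":
        rows = g.row_index(spec.subset) if spec.subset is not None else slice(None)
        return np.asarray(g.matrix[rows, :].sum(axis=0), dtype=np.int64)
    cols = g.col_index(spec.subset) if spec.subset is not None else slice(None)
    return np.asarray(g.matrix[:, cols].sum(axis=1), dtype=np.int64)


def count_motifs(g: BipartiteGraph, spec: MotifSpec) -> int:
    """Number of order-``n`` motifs: ``sum over opposite layer of binom(k, n)``
    where ``k`` is the (subset-restricted) degree; ``binom(k, n) = 0`` for
    ``k < n``.  Order 1 returns the number of links incident to the subset."""
    k = restricted_degrees(g, spec)
    return int(comb(k, spec.order, exact=False).round().sum())


# ---------------------------------------------------------------------------
# Assortativity coefficient
# ---------------------------------------------------------------------------

def assortativity_coefficient(g: BipartiteGraph) -> float | None:
    """Degree–degree Pearson correlation over links, in ``[-1, 1]``.

    Each link contributes the pair ``(d_c, u_p)`` of its endpoint degrees.
    Returns ``None`` when the correlation is undefined (fewer than two
    links, or zero degree variance on either side across links, as in any
    biregular or complete graph).
    """
    c_idx, p_idx = np.nonzero(g.matrix)
    if c_idx.size < 2:
        return None
    x = g.row_degrees[c_idx].astype(float)
    y = g.col_degrees[p_idx].astype(float)
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return None
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


# ---------------------------------------------------------------------------
# Nestedness (NODF)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NestednessResult:
    """NODF nestedness percentages, total and per-layer components."""

    nodf_total: float
    nodf_rows: float
    nodf_cols: float

    def to_dict(self) -> dict:
        return {
            "nodf_total": self.nodf_total,
            "nodf_rows": self.nodf_rows,
            "nodf_cols": self.nodf_cols,
        }


def _nodf_pair_sum(m: np.ndarray) -> tuple[float, int]:
    """Sum of paired-overlap percentages over all unordered row pairs.

    A pair (i, j) with ``d_i > d_j > 0`` contributes
    ``100 * |N(i) ∩ N(j)| / d_j``; equal or zero degrees contribute 0
    (decreasing-fill condition).  Returns ``(sum, n_pairs)``.
    """
    d = m.sum(axis=1).astype(float)
    overlap = (m @ m.T).astype(float)
    di = d[:, None]
    dj = d[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = np.where((di > dj) & (dj > 0), 100.0 * overlap / dj, 0.0)
    n = m.shape[0]
    return float(contrib.sum()), n * (n - 1) // 2


def nodf(g: BipartiteGraph) -> NestednessResult:
    """NODF nestedness of the biadjacency matrix (0–100 scale).

    Invariant under row and column permutations: the decreasing-fill
    condition compares marginal totals, not positions.
    """
    if g.n_rows < 2 and g.n_cols < 2:
        raise ValueError("NODF undefined for a single-node-per-layer graph")
    m = g.matrix.astype(np.int64)
    row_sum, row_pairs = _nodf_pair_sum(m)
    col_sum, col_pairs = _nodf_pair_sum(m.T)
    return NestednessResult(
        nodf_total=(row_sum + col_sum) / (row_pairs + col_pairs),
        nodf_rows=row_sum / row_pairs if row_pairs else float("nan"),
        nodf_cols=col_sum / col_pairs if col_pairs else float("nan"),
    )


# ---------------------------------------------------------------------------
# Fitness and complexity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitnessComplexityResult:
    """Converged fitness (rows) and complexity (columns) vectors.

    Zero-degree nodes carry NaN; the defined entries of each vector are
    normalized to unit mean.  ``trace`` records the max relative change per
    iteration, so non-convergence (a known behavior of the map on some
    matrices) is visible rather than hidden.
    """

    fitness: np.ndarray
    complexity: np.ndarray
    n_iterations: int
    converged: bool
    trace: np.ndarray = field(repr=False)
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "fitness": dict(zip(self.row_labels, self.fitness.tolist())),
            "complexity": dict(zip(self.col_labels, self.complexity.tolist())),
            "n_iterations": self.n_iterations,
            "converged": self.converged,
        }


def fitness_complexity(
    g: BipartiteGraph, tol: float = 1e-8, max_iter: int = 1000
) -> FitnessComplexityResult:
    """Iterate the fitness–complexity map to a fixed point.

    Starting from all-ones, each step computes

    ``F~_c = sum_p m_cp Q_p``  and  ``Q~_p = 1 / sum_c m_cp / F_c``

    then rescales both vectors to unit mean.  Iteration stops when the max
    relative change of both vectors drops below ``tol`` or after
    ``max_iter`` steps (flagged via ``converged``).  Zero-degree nodes are
    excluded from the iteration (they would divide by zero) and reported as
    NaN.
    """
    active_r = g.row_degrees > 0
    active_c = g.col_degrees > 0
    if not active_r.any() or not active_c.any():
        raise ValueError("fitness-complexity undefined on an empty graph")
    if (~active_r).any() or (~active_c).any():
        logger.info(
            "fitness-complexity: excluding %d zero-degree row(s) and %d column(s)",
            int((~active_r).sum()),
            int((~active_c).sum()),
        )
    m = g.matrix[np.ix_(active_r, active_c)].astype(float)
    F = np.ones(m.shape[0])
    Q = np.ones(m.shape[1])
    trace = []
    converged = False
    n_done = 0
    for n_done in range(1, max_iter + 1):
        F_new = m @ Q
        Q_new = 1.0 / (m.T @ (1.0 / F))
        F_new /= F_new.mean()
        Q_new /= Q_new.mean()
        delta = max(
            np.max(np.abs(F_new - F) / F),
            np.max(np.abs(Q_new - Q) / Q),
        )
        trace.append(delta)
        F, Q = F_new, Q_new
        if delta < tol:
            converged = True
            break
    fitness = np.full(g.n_rows, np.nan)
    complexity = np.full(g.n_cols, np.nan)
    fitness[active_r] = F
    complexity[active_c] = Q
    return FitnessComplexityResult(
        fitness=fitness,
        complexity=complexity,
        n_iterations=n_done,
        converged=converged,
        trace=np.array(trace),
        row_labels=g.row_labels,
        col_labels=g.col_labels,
    )


def rank_by_fitness(
    g: BipartiteGraph, fc: FitnessComplexityResult | None = None
) -> BipartiteGraph:
    """Reorder rows by decreasing fitness and columns by increasing
    complexity, the ordering that exposes the triangular (nested) shape of
    the matrix.  NaN entries (zero-degree nodes) sort last/first so they
    sit at the sparse corner."""
    if fc is None:
        fc = fitness_complexity(g)
    # NaN-safe sort keys: isolated rows go last, isolated columns first
    f_key = np.where(np.isnan(fc.fitness), -np.inf, fc.fitness)
    q_key = np.where(np.isnan(fc.complexity), -np.inf, fc.complexity)
    row_order = np.argsort(-f_key, kind="stable")
    col_order = np.argsort(q_key, kind="stable")
    return BipartiteGraph(
        tuple(g.row_labels[i] for i in row_order),
        tuple(g.col_labels[j] for j in col_order),
        g.matrix[np.ix_(row_order, col_order)],
    )
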