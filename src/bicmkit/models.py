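"""Maximum-entropy null models for binary bipartite networks.

The bipartite configuration model (BiCM) is the distribution over all
``2^(C*P)`` binary biadjacency matrices that maximizes Shannon entropy

``S = - sum_M P(M) ln P(M)``

subject to the expected degree sequences of both layers matching the
observed ones.  The constrained maximization yields an exponential family
in which every link is an independent Bernoulli variable:

``P(M) = prod_{c,p} p_cp^{m_cp} (1 - p_cp)^{1 - m_cp}``,
``p_cp = x_c y_p / (1 + x_c y_p)``,

with one hidden variable (exponentiated Lagrange multiplier) per node.
The hidden variables are estimated by maximizing the log-likelihood of the
observed matrix,

``LL = sum_c d_c ln x_c + sum_p u_p ln y_p - sum_{c,p} ln(1 + x_c y_p)``,

whose stationarity conditions are exactly the ``C + P`` constraint
equations ``<d_c> = d_c`` and ``<u_p> = u_p``.

The bipartite random graph (BiRG) is the one-constraint special case: only
the expected number of links is fixed, giving a single probability
``p = L / (C * P)`` for every pair.

Because the measure factorizes over pairs, expectations of the motif
counts are elementary symmetric polynomials of the link probabilities, and
the ensemble Shannon entropy per pair reduces to the mean Bernoulli
entropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy import optimize

from bicmkit.core import BipartiteGraph
from bicmkit.observables import MotifSpec

__all__ = [
    "BicmModel",
    "BirgModel",
    "SolverError",
    "fit_bicm",
    "fit_birg",
    "solve_bicm",
    "matrix_probability",
    "expected_motif_mean",
    "expected_motif_std",
    "expected_degrees",
    "ensemble_entropy",
    "elementary_symmetric",
    "NEG_INF",
]

NEG_INF = float("-inf")


class SolverError(RuntimeError):
    """Raised when the likelihood maximization fails to reach tolerance."""

    def __init__(self, message: str, residual_trace: np.ndarray):
        super().__init__(message)
        self.residual_trace = residual_trace


@dataclass(frozen=True)
class BicmModel:
    """A fitted bipartite configuration model.

    ``x``/``y`` are the hidden variables per row/column (NaN for nodes
    whose probabilities were fixed to 0 or 1 by the degenerate-degree
    limits); ``link_prob`` is the full ``C x P`` matrix of independent
    Bernoulli link probabilities.
    """

    x: np.ndarray
    y: np.ndarray
    link_prob: np.ndarray = field(repr=False)
    loglik: float
    max_degree_residual: float
    solver_info: dict
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    @property
    def shape(self) -> tuple[int, int]:
        return self.link_prob.shape

    def to_dict(self) -> dict:
        return {
            "model": "bicm",
            "x": dict(zip(self.row_labels, self.x.tolist())),
            "y": dict(zip(self.col_labels, self.y.tolist())),
            "loglik": self.loglik,
            "max_degree_residual": self.max_degree_residual,
            "solver_info": dict(self.solver_info),
        }


@dataclass(frozen=True)
class BirgModel:
    """Bipartite random graph: one link probability for every pair."""

    p: float
    n_rows: int
    n_cols: int
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def link_prob(self) -> np.ndarray:
        return np.full((self.n_rows, self.n_cols), self.p)

    def to_dict(self) -> dict:
        return {
            "model": "birg",
            "p": self.p,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
        }


Model = Union[BicmModel, BirgModel]


# ---------------------------------------------------------------------------
# BiCM likelihood maximization
# ---------------------------------------------------------------------------

def _reduce_classes(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique degree values, multiplicities, and inverse index."""
    uniq, inverse, counts = np.unique(values, return_inverse=True, return_counts=True)
    return uniq, counts.astype(float), inverse


def _class_fixed_point(
    d: np.ndarray,
    nd: np.ndarray,
    u: np.ndarray,
    nu: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, str]:
    """Solve the degree-constraint system on degree equivalence classes.

    Unknowns are one hidden variable per distinct row degree ``d`` (with
    multiplicity ``nd``) and per distinct column degree ``u`` (``nu``).
    Iterates ``x_i <- d_i / sum_j nu_j y_j / (1 + x_i y_j)`` and the
    symmetric column update; falls back to a least-squares root find on
    log-parameters if the fixed point stalls.
    """
    L = float((d * nd).sum())
    x = d / math.sqrt(L)
    y = u / math.sqrt(L)
    residuals = []
    method = "fixed-point"

    def residual(x: np.ndarray, y: np.ndarray) -> float:
        p = _outer_prob(x, y)
        return max(
            np.max(np.abs(p @ nu - d)),
            np.max(np.abs(nd @ p - u)),
        )

    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        denom_x = (nu[None, :] * y[None, :] / (1.0 + np.outer(x, y))).sum(axis=1)
        x = d / denom_x
        denom_y = (nd[:, None] * x[:, None] / (1.0 + np.outer(x, y))).sum(axis=0)
        y = u / denom_y
        res = residual(x, y)
        residuals.append(res)
        if res <= tol:
            return x, y, np.array(residuals), n_iter, method

    # quasi-Newton fallback on log-parameters (positivity preserved)
    method = "fixed-point+newton"

    def fun(z: np.ndarray) -> np.ndarray:
        xx = np.exp(z[: d.size])
        yy = np.exp(z[d.size :])
        p = _outer_prob(xx, yy)
        return np.concatenate([p @ nu - d, nd @ p - u])

    sol = optimize.root(fun, np.log(np.concatenate([x, y])), method="lm")
    x = np.exp(sol.x[: d.size])
    y = np.exp(sol.x[d.size :])
    res = residual(x, y)
    residuals.append(res)
    if res > tol:
        raise SolverError(
            f"BiCM solver failed to reach tolerance {tol:g} "
            f"(final residual {res:g})",
            np.array(residuals),
        )
    return x, y, np.array(residuals), n_iter + sol.nfev, method


def _outer_prob(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xy = np.outer(x, y)
    return xy / (1.0 + xy)


def solve_bicm(
    d: np.ndarray,
    u: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Fit BiCM hidden variables to (possibly non-integer) target degrees.

    Returns ``(x, y, link_prob, solver_info)``.  Degenerate degrees are
    resolved by taking the corresponding multiplier limits before solving:
    a zero-degree node gets probability 0 on its whole line, a saturated
    node (degree equal to the size of the opposite layer) probability 1 —
    either limit satisfies its constraint equation exactly — and the
    remaining core system is solved on degree equivalence classes.
    Saturation is peeled iteratively, since removing a full line can
    saturate or empty further nodes.
    """
    d = np.asarray(d, dtype=float)
    u = np.asarray(u, dtype=float)
    C, P = d.size, u.size
    if (d < 0).any() or (u < 0).any():
        raise ValueError("degrees must be nonnegative")
    if d.sum() > 0 and not math.isclose(d.sum(), u.sum(), rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError("row and column degree totals must coincide")

    p = np.full((C, P), np.nan)
    x_full = np.full(C, np.nan)
    y_full = np.full(P, np.nan)
    active_r = np.ones(C, dtype=bool)
    active_c = np.ones(P, dtype=bool)
    dr = d.copy()
    uc = u.copy()
    eps = max(tol, 1e-12)

    # peel zero-degree and saturated nodes until the core is non-degenerate
    changed = True
    while changed:
        changed = False
        n_ac = int(active_c.sum())
        for i in np.flatnonzero(active_r):
            if dr[i] <= eps:
                p[i, active_c] = 0.0
                active_r[i] = False
                changed = True
            elif dr[i] >= n_ac - eps:
                p[i, active_c] = 1.0
                uc[active_c] -= 1.0
                active_r[i] = False
                changed = True
        n_ar = int(active_r.sum())
        for j in np.flatnonzero(active_c):
            if uc[j] <= eps:
                p[active_r, j] = 0.0
                active_c[j] = False
                changed = True
            elif uc[j] >= n_ar - eps:
                p[active_r, j] = 1.0
                dr[active_r] -= 1.0
                active_c[j] = False
                changed = True

    info: dict = {"method": "degenerate-limits", "iterations": 0}
    if active_r.any() and active_c.any():
        dcore = dr[active_r]
        ucore = uc[active_c]
        du, nd, dinv = _reduce_classes(dcore)
        uu, nu, uinv = _reduce_classes(ucore)
        xc, yc, res_trace, n_iter, method = _class_fixed_point(
            du, nd, uu, nu, tol, max_iter
        )
        x_core = xc[dinv]
        y_core = yc[uinv]
        x_full[active_r] = x_core
        y_full[active_c] = y_core
        p[np.ix_(active_r, active_c)] = _outer_prob(x_core, y_core)
        info = {
            "method": method,
            "iterations": int(n_iter),
            "n_row_classes": int(du.size),
            "n_col_classes": int(uu.size),
        }
    assert not np.isnan(p).any()

    info["max_degree_residual"] = float(
        max(np.max(np.abs(p.sum(axis=1) - d)), np.max(np.abs(p.sum(axis=0) - u)))
    )
    return x_full, y_full, p, info


def _bernoulli_loglik(m: np.ndarray, p: np.ndarray) -> float:
    """``sum m log p + (1-m) log(1-p)`` with the ``0 * log 0 = 0`` convention;
    ``-inf`` if an impossible entry is observed."""
    ones = m == 1
    zeros = ~ones
    if (p[ones] == 0).any() or (p[zeros] == 1).any():
        return NEG_INF
    out = 0.0
    po = p[ones]
    pz = p[zeros]
    out += float(np.log(po[po > 0]).sum())
    out += float(np.log1p(-pz[pz < 1]).sum())
    return out


def fit_bicm(
    g: BipartiteGraph, tol: float = 1e-8, max_iter: int = 5000
) -> BicmModel:
    """Fit the BiCM to a graph's degree sequences by likelihood maximization.

    Deterministic (no randomness) and independent of node ordering: nodes
    with equal degree receive identical hidden variables because the
    reduced system is solved per degree class.
    """
    x, y, p, info = solve_bicm(
        g.row_degrees.astype(float), g.col_degrees.astype(float), tol, max_iter
    )
    return BicmModel(
        x=x,
        y=y,
        link_prob=p,
        loglik=_bernoulli_loglik(g.matrix, p),
        max_degree_residual=info["max_degree_residual"],
        solver_info=info,
        row_labels=g.row_labels,
        col_labels=g.col_labels,
    )


def fit_birg(g: BipartiteGraph) -> BirgModel:
    """Fit the bipartite random graph: ``p = L / (C * P)`` (the connectance)."""
    return BirgModel(
        p=g.n_links / (g.n_rows * g.n_cols),
        n_rows=g.n_rows,
        n_cols=g.n_cols,
        row_labels=g.row_labels,
        col_labels=g.col_labels,
    )


# ---------------------------------------------------------------------------
# Ensemble expectations
# ---------------------------------------------------------------------------

def matrix_probability(model: Model, m: BipartiteGraph | np.ndarray) -> float:
    """Log-probability of one matrix under the factorized ensemble measure.

    Returns ``-inf`` (sentinel) if the matrix places a link where the model
    forbids one, or omits a link the model forces.
    """
    mat = m.matrix if isinstance(m, BipartiteGraph) else np.asarray(m)
    if mat.shape != model.shape:
        raise ValueError(
            f"matrix shape {mat.shape} does not match model shape {model.shape}"
        )
    return _bernoulli_loglik(mat, np.asarray(model.link_prob, dtype=float))


def elementary_symmetric(p: np.ndarray, n: int) -> float:
    """n-th elementary symmetric polynomial ``e_n`` of the values ``p``.

    Computed by the stable recurrence ``e_n(k) = e_n(k-1) + p_k e_{n-1}(k-1)``;
    this is the expectation of ``binom(S, n)`` for a sum ``S`` of independent
    Bernoulli(p_k) variables.
    """
    if n == 0:
        return 1.0
    p = np.asarray(p, dtype=float)
    if n > p.size:
        return 0.0
    e = np.zeros(n + 1)
    e[0] = 1.0
    for pk in p:
        e[1 : n + 1] += pk * e[0:n]
    return float(e[n])


def _motif_prob_lines(model: Model, spec: MotifSpec) -> np.ndarray:
    """Link-probability lines over which the motif's tuples form.

    For a V spec: one column of probabilities per column node, restricted
    to the subset rows.  For Lambda: one row per row node, restricted to
    the subset columns.  Returns an array of shape (n_lines, tuple_pool).
    """
    p = np.asarray(model.link_prob, dtype=float)
    if spec.family == "V":
        if spec.subset is not None:
            idx = _subset_index(model, spec, axis=0)
            p = p[idx, :]
        return p.T
    if spec.subset is not None:
        idx = _subset_index(model, spec, axis=1)
        p = p[:, idx]
    return p


def _subset_index(model: Model, spec: MotifSpec, axis: int) -> np.ndarray:
    labels = model.row_labels if axis == 0 else model.col_labels
    if not labels:
        raise ValueError("model carries no labels; cannot resolve motif subset")
    lookup = {lab: i for i, lab in enumerate(labels)}
    try:
        return np.array([lookup[lab] for lab in spec.subset], dtype=np.intp)
    except KeyError as exc:
        raise KeyError(f"unknown subset label: {exc.args[0]!r}") from None


def expected_motif_mean(model: Model, spec: MotifSpec) -> float:
    """Exact ensemble mean of a motif count.

    Links are independent, so the number of order-``n`` tuples through one
    line (a column for V, a row for Lambda) has expectation
    ``e_n`` of that line's link probabilities; the total is the sum over
    lines.  Order 1 reduces to the expected number of links.
    """
    lines = _motif_prob_lines(model, spec)
    return float(sum(elementary_symmetric(line, spec.order) for line in lines))


def expected_motif_std(model: Model, spec: MotifSpec) -> float | None:
    """Exact ensemble standard deviation of a motif count, orders 1 and 2.

    Lines are independent, so variances add.  For order 1 the per-line
    variance is ``sum p (1 - p)``.  For order 2 the count through one line
    is ``binom(S, 2)`` with ``S`` a Poisson-binomial sum; its factorial
    moments are ``E[(S)_k] = k! e_k``, and the identity
    ``[(S)_2]^2 = (S)_4 + 4 (S)_3 + 2 (S)_2`` gives

    ``Var = 6 e_4 + 6 e_3 + e_2 - e_2^2``  per line.

    Returns ``None`` for orders >= 3, where the package defers to ensemble
    sampling (see :mod:`bicmkit.ensemble`).
    """
    if spec.order > 2:
        return None
    lines = _motif_prob_lines(model, spec)
    var = 0.0
    if spec.order == 1:
        for line in lines:
            var += float((line * (1.0 - line)).sum())
    else:
        for line in lines:
            e2 = elementary_symmetric(line, 2)
            e3 = elementary_symmetric(line, 3)
            e4 = elementary_symmetric(line, 4)
            var += 6.0 * e4 + 6.0 * e3 + e2 - e2 * e2
    return math.sqrt(max(var, 0.0))


def expected_degrees(model: Model) -> tuple[np.ndarray, np.ndarray]:
    """Row and column sums of the link-probability matrix.

    For a fitted BiCM these equal the observed degree sequences within the
    solver tolerance (the defining constraints of the model)."""
    p = np.asarray(model.link_prob, dtype=float)
    return p.sum(axis=1), p.sum(axis=0)


def ensemble_entropy(model: Model) -> float:
    """Shannon entropy of the ensemble measure per node pair.

    ``S = -(1/(C P)) sum_cp [p ln p + (1-p) ln(1-p)]`` with
    ``0 ln 0 = 0``; bounded above by ``ln 2`` (the uniform measure).
    Deterministic models (all probabilities 0 or 1) have zero entropy.
    """
    p = np.asarray(model.link_prob, dtype=float).ravel()
    inner = np.zeros_like(p)
    mask = (p > 0) & (p < 1)
    pm = p[mask]
    inner[mask] = pm * np.log(pm) + (1.0 - pm) * np.log1p(-pm)
    return float(-inner.mean())
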