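"""Synthetic bipartite fixtures with controlled structure.

Four generator kinds cover the regimes the null models are exercised on:

``hidden_variable``
    Draws each pair independently with probability
    ``x_c y_p / (1 + x_c y_p)`` where the hidden variables are sampled from
    a lognormal law (heavy-tailed, so both layers get heterogeneous,
    right-skewed degree sequences like real trade or mutualistic
    matrices) and rescaled so the expected connectance hits a target.
``nested``
    Fills a triangular region — row ``i`` (of ``C``) links the first
    ``round(2 * fill * P * ((C - i) / C) ** shape)`` columns (clipped to
    ``[1, P]``) — then deletes each filled cell with a small noise
    probability, always retaining every row's first (most ubiquitous)
    link.  Deletion noise thins baskets without ever creating links
    between low-degree rows and rare columns, so low-degree rows stay
    attached exclusively to ubiquitous columns: the matrices are
    high-NODF and *more* disassortative than their degree sequence
    forces, like fitness/complexity-ordered trade or mutualistic
    incidence matrices.  ``shape > 1`` curves the boundary.
``biregular``
    Circulant design with every row at exactly ``row_degree``; exactly
    biregular when ``C * row_degree`` is a multiple of ``P``.
``random_uniform``
    Homogeneous Bernoulli(``p``) matrix (the BiRG measure itself).

All kinds are seed-deterministic: identical configs give identical
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from bicmkit.core import BipartiteGraph

__all__ = ["GeneratorConfig", "generate", "sample_hidden_variables"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of one synthetic fixture.

    ``params`` by kind (unknown keys are rejected):

    hidden_variable: ``sigma`` (lognormal shape, default 1.0),
        ``connectance`` (target expected fill, default 0.1)
    nested: ``fill`` (approximate connectance of the triangle, default
        0.5, in (0, 1]), ``noise`` (per-link deletion probability,
        default 0.0), ``shape`` (boundary curvature exponent, default 1.0)
    biregular: ``row_degree`` (required, 1..P)
    random_uniform: ``p`` (required, in [0, 1])
    """

    kind: Literal["hidden_variable", "nested", "biregular", "random_uniform"]
    n_rows: int
    n_cols: int
    seed: int = 0
    params: dict = field(default_factory=dict)

    _ALLOWED = {
        "hidden_variable": {"sigma", "connectance"},
        "nested": {"fill", "noise", "shape"},
        "biregular": {"row_degree"},
        "random_uniform": {"p"},
    }

    def __post_init__(self) -> None:
        if self.kind not in self._ALLOWED:
            raise ValueError(f"unknown generator kind {self.kind!r}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("layer sizes must be >= 1")
        unknown = set(self.params) - self._ALLOWED[self.kind]
        if unknown:
            raise ValueError(
                f"unknown parameter(s) {sorted(unknown)} for kind {self.kind!r}"
            )


def sample_hidden_variables(
    n_rows: int,
    n_cols: int,
    rng: np.random.Generator,
    sigma: float = 1.0,
    connectance: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Lognormal hidden variables rescaled to a target expected connectance.

    Both layers get ``exp(N(0, sigma^2))`` weights; a scalar multiplier on
    the product ``x_c y_p`` is then bisected so that the mean of
    ``x y / (1 + x y)`` over all pairs equals ``connectance``.
    """
    if not 0 < connectance < 1:
        raise ValueError("connectance must be in (0, 1)")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    x = rng.lognormal(mean=0.0, sigma=sigma, size=n_rows)
    y = rng.lognormal(mean=0.0, sigma=sigma, size=n_cols)
    xy = np.outer(x, y)

    def mean_p(scale: float) -> float:
        s = scale * xy
        return float((s / (1.0 + s)).mean())

    lo, hi = 1e-12, 1e12
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if mean_p(mid) < connectance:
            lo = mid
        else:
            hi = mid
    scale = np.sqrt(lo * hi)
    return x * np.sqrt(scale), y * np.sqrt(scale)


def _nested_matrix(
    C: int, P: int, fill: float, noise: float, shape: float, rng: np.random.Generator
) -> np.ndarray:
    if not 0 < fill <= 1:
        raise ValueError("fill must be in (0, 1]")
    if not 0 <= noise < 1:
        raise ValueError("noise must be in [0, 1)")
    if shape <= 0:
        raise ValueError("shape must be positive")
    m = np.zeros((C, P), dtype=np.int8)
    for i in range(C):
        d = int(round(2.0 * fill * P * ((C - i) / C) ** shape))
        m[i, : min(max(d, 1), P)] = 1
    if noise > 0:
        deletions = (rng.random((C, P)) < noise) & (m == 1)
        deletions[:, 0] = False  # every row keeps its most ubiquitous link
        m[deletions] = 0
    return m


def _biregular_matrix(C: int, P: int, row_degree: int) -> np.ndarray:
    if not 1 <= row_degree <= P:
        raise ValueError(f"row_degree must be in 1..{P}")
    if (C * row_degree) % P != 0:
        raise ValueError(
            f"C * row_degree = {C * row_degree} must be a multiple of P = {P} "
            "for a biregular graph"
        )
    m = np.zeros((C, P), dtype=np.int8)
    pos = 0
    for i in range(C):
        for _ in range(row_degree):
            m[i, pos % P] = 1
            pos += 1
    return m


def generate(cfg: GeneratorConfig) -> BipartiteGraph:
    """Generate a labeled synthetic biadjacency matrix from a config."""
    rng = np.random.default_rng(cfg.seed)
    C, P = cfg.n_rows, cfg.n_cols
    if cfg.kind == "hidden_variable":
        x, y = sample_hidden_variables(
            C,
            P,
            rng,
            sigma=float(cfg.params.get("sigma", 1.0)),
            connectance=float(cfg.params.get("connectance", 0.1)),
        )
        p = np.outer(x, y)
        p = p / (1.0 + p)
        m = (rng.random((C, P)) < p).astype(np.int8)
    elif cfg.kind == "nested":
        m = _nested_matrix(
            C,
            P,
            float(cfg.params.get("fill", 0.5)),
            float(cfg.params.get("noise", 0.0)),
            float(cfg.params.get("shape", 1.0)),
            rng,
        )
    elif cfg.kind == "biregular":
        if "row_degree" not in cfg.params:
            raise ValueError("biregular generator requires params['row_degree']")
        m = _biregular_matrix(C, P, int(cfg.params["row_degree"]))
    else:  # random_uniform
        if "p" not in cfg.params:
            raise ValueError("random_uniform generator requires params['p']")
        p = float(cfg.params["p"])
        if not 0 <= p <= 1:
            raise ValueError("p must be in [0, 1]")
        m = (rng.random((C, P)) < p).astype(np.int8)
    return BipartiteGraph.from_matrix(m)
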