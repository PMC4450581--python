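"""Sampling the grandcanonical ensemble and significance statistics.

A fitted model assigns every node pair an independent Bernoulli link
probability, so a draw from the ensemble is a matrix of independent coin
flips.  Observables are evaluated per draw and reduced on the fly
(constant memory in the number of draws unless matrices are explicitly
requested), giving sampling estimates of the ensemble mean and standard
deviation of any observable:

``<X> ~= (1/n) sum_i X(M_i)``,  ``sigma_X ~= sqrt((1/n) sum_i X(M_i)^2 - <X>^2)``.

Averaging over draws weights every distinct matrix by its sampled
frequency, which converges to the ensemble probability because the
sampler is unbiased.

For a motif with observed abundance ``N*``, ensemble mean ``<N>`` and
standard deviation ``sigma``, the module reports

* the z-score ``z = (N* - <N>) / sigma`` — significance of the deviation,
* the similarity ``s = (N* - <N>) / <N>`` — relative size of the deviation,

whose ratio ``s / z = sigma / <N>`` is the motif's ensemble coefficient of
variation.  If the model reproduced the observation exactly, both would be
zero.  Default significance thresholds are ``|z| > 1.65`` for the
aggregated motif families and ``|z| > 2`` for subset-restricted motifs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np
from scipy import stats

from bicmkit.core import BipartiteGraph
from bicmkit.models import (
    BicmModel,
    BirgModel,
    expected_motif_mean,
    expected_motif_std,
)
from bicmkit.observables import (
    MotifSpec,
    assortativity_coefficient,
    count_motifs,
    fitness_complexity,
    nodf,
)

__all__ = [
    "EnsembleSample",
    "MotifReport",
    "sample",
    "sampling_moments",
    "motif_report",
    "distribution_summary",
    "observable_report",
    "draw_matrix",
    "Z0_GLOBAL",
    "Z0_SUBSET",
]

Model = Union[BicmModel, BirgModel]

Z0_GLOBAL = 1.65
Z0_SUBSET = 2.0

DEFAULT_N_DRAWS = 5000


# ---------------------------------------------------------------------------
# Observable registry
# ---------------------------------------------------------------------------

def _obs_n_links(m: np.ndarray) -> float:
    return float(m.sum())


def _obs_r(m: np.ndarray) -> float:
    r = assortativity_coefficient(BipartiteGraph.from_matrix(m))
    return math.nan if r is None else r


def _obs_nodf(which: str) -> Callable[[np.ndarray], float]:
    def f(m: np.ndarray) -> float:
        res = nodf(BipartiteGraph.from_matrix(m))
        return getattr(res, which)

    return f


def _obs_anpu(m: np.ndarray) -> np.ndarray:
    d = m.sum(axis=1).astype(float)
    u = m.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(d > 0, (m @ u) / d, np.nan)


def _obs_ancd(m: np.ndarray) -> np.ndarray:
    return _obs_anpu(m.T)


def _obs_mean(vec_fn: Callable[[np.ndarray], np.ndarray]) -> Callable[[np.ndarray], float]:
    def f(m: np.ndarray) -> float:
        v = vec_fn(m)
        v = v[~np.isnan(v)]
        return float(v.mean()) if v.size else math.nan

    return f


def _ranked(values: np.ndarray, size: int) -> np.ndarray:
    """Defined values sorted descending, NaN-padded to ``size``."""
    v = np.sort(values[~np.isnan(values)])[::-1]
    out = np.full(size, np.nan)
    out[: v.size] = v
    return out


def _obs_fitness_ranked(m: np.ndarray) -> np.ndarray:
    g = BipartiteGraph.from_matrix(m)
    if not (g.row_degrees > 0).any() or not (g.col_degrees > 0).any():
        return np.full(m.shape[0], np.nan)
    fc = fitness_complexity(g, tol=1e-7, max_iter=300)
    return _ranked(fc.fitness, m.shape[0])


def _obs_complexity_ranked(m: np.ndarray) -> np.ndarray:
    g = BipartiteGraph.from_matrix(m)
    if not (g.row_degrees > 0).any() or not (g.col_degrees > 0).any():
        return np.full(m.shape[1], np.nan)
    fc = fitness_complexity(g, tol=1e-7, max_iter=300)
    return _ranked(fc.complexity, m.shape[1])


_SCALAR_OBS: dict[str, Callable[[np.ndarray], float]] = {
    "n_links": _obs_n_links,
    "assortativity_r": _obs_r,
    "nodf_total": _obs_nodf("nodf_total"),
    "nodf_rows": _obs_nodf("nodf_rows"),
    "nodf_cols": _obs_nodf("nodf_cols"),
    "mean_anpu": _obs_mean(_obs_anpu),
    "mean_ancd": _obs_mean(_obs_ancd),
}

_VECTOR_OBS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "anpu": _obs_anpu,
    "ancd": _obs_ancd,
    "degrees_rows": lambda m: m.sum(axis=1).astype(float),
    "degrees_cols": lambda m: m.sum(axis=0).astype(float),
    "fitness_ranked": _obs_fitness_ranked,
    "complexity_ranked": _obs_complexity_ranked,
}

ObservableSpec = Union[str, MotifSpec]


def _resolve(spec: ObservableSpec) -> tuple[str, Callable[[np.ndarray], float | np.ndarray]]:
    if isinstance(spec, MotifSpec):
        def f(m: np.ndarray, _spec: MotifSpec = spec) -> float:
            return float(count_motifs(BipartiteGraph.from_matrix(m), _spec))

        return f"motif_{spec.name}", f
    if spec in _SCALAR_OBS:
        return spec, _SCALAR_OBS[spec]
    if spec in _VECTOR_OBS:
        return spec, _VECTOR_OBS[spec]
    raise ValueError(
        f"unknown observable {spec!r}; known: "
        f"{sorted(_SCALAR_OBS) + sorted(_VECTOR_OBS)} or a MotifSpec"
    )


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def draw_matrix(model: Model, seed_or_rng: int | np.random.Generator) -> np.ndarray:
    """Draw one binary matrix: every pair independently 1 with ``p_cp``."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    p = np.asarray(model.link_prob, dtype=float)
    return (rng.random(p.shape) < p).astype(np.int8)


def _draw_rng(seed: int, index: int) -> np.random.Generator:
    # per-draw substream: deterministic in (seed, index), independent across
    # draws, so extending the observable set never changes earlier draws
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(index))))


@dataclass(frozen=True)
class EnsembleSample:
    """Per-draw observable values from a sampled grandcanonical ensemble.

    ``draws`` maps each resolved observable name to an array whose first
    axis is the draw index.  Identical (model, seed, n_draws) triples give
    bit-identical samples.
    """

    model_ref: str
    n_draws: int
    seed: int
    draws: dict[str, np.ndarray] = field(repr=False)
    matrices: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "model_ref": self.model_ref,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "draws": {k: v.tolist() for k, v in self.draws.items()},
        }


def sample(
    model: Model,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
    observables: Sequence[ObservableSpec] = ("n_links",),
    keep_matrices: bool = False,
) -> EnsembleSample:
    """Sample the ensemble and evaluate observables per draw.

    Matrices are generated and reduced one at a time; set
    ``keep_matrices=True`` to also retain the raw draws (memory grows with
    ``n_draws * C * P``).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    resolved = [_resolve(spec) for spec in observables]  # fail fast
    names = [name for name, _ in resolved]
    if len(set(names)) != len(names):
        raise ValueError("duplicate observables requested")
    columns: dict[str, list] = {name: [] for name in names}
    kept = [] if keep_matrices else None
    for i in range(n_draws):
        m = draw_matrix(model, _draw_rng(seed, i))
        if kept is not None:
            kept.append(m)
        for name, fn in resolved:
            columns[name].append(fn(m))
    return EnsembleSample(
        model_ref=type(model).__name__,
        n_draws=n_draws,
        seed=int(seed),
        draws={name: np.asarray(vals) for name, vals in columns.items()},
        matrices=np.asarray(kept) if kept is not None else None,
    )


def sampling_moments(s: EnsembleSample, observable: str) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic mean and population standard deviation over draws.

    NaN entries (undefined per-draw values, e.g. ranks beyond the number
    of non-isolated nodes in a draw) are excluded per component.
    """
    if observable not in s.draws:
        raise KeyError(
            f"observable {observable!r} was not requested at sampling time"
        )
    if s.n_draws < 2:
        raise ValueError("at least 2 draws are required for moment estimates")
    values = s.draws[observable]
    import warnings

    with warnings.catch_warnings():
        # components undefined in every draw (e.g. trailing ranks) are NaN
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        warnings.filterwarnings("ignore", message="Degrees of freedom <= 0")
        mean = np.nanmean(values, axis=0)
        std = np.nanstd(values, axis=0, ddof=0)
    return mean, std


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifReport:
    """Observed vs expected abundance of one motif family.

    ``z_score`` is ``inf``-signed when the ensemble std is zero but the
    observation deviates; ``similarity`` is NaN when the expected abundance
    is zero.  ``moment_source`` records whether the std came from the
    closed form (orders <= 2) or from sampling.
    """

    motif: str
    observed: float
    expected: float
    std: float
    z_score: float
    similarity: float
    cv: float
    z0: float
    significant: bool
    moment_source: str

    def to_dict(self) -> dict:
        return {
            "motif": self.motif,
            "observed": self.observed,
            "expected": self.expected,
            "std": self.std,
            "z_score": self.z_score,
            "similarity": self.similarity,
            "cv": self.cv,
            "z0": self.z0,
            "significant": self.significant,
            "moment_source": self.moment_source,
        }


def _safe_z(observed: float, expected: float, std: float) -> float:
    # a std at accumulation-roundoff scale means a degenerate ensemble
    tiny = 1e-12 * (1.0 + abs(expected))
    if std > tiny:
        return (observed - expected) / std
    if abs(observed - expected) <= tiny:
        return 0.0
    return math.copysign(math.inf, observed - expected)


def motif_report(
    g: BipartiteGraph,
    model: Model,
    spec: MotifSpec,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
    z0: float | None = None,
) -> MotifReport:
    """Score one motif family against the null ensemble.

    The expected abundance is always analytic (elementary symmetric
    polynomials of the link probabilities); the standard deviation is
    analytic for orders 1–2 and estimated by sampling ``n_draws`` matrices
    for higher orders.
    """
    if z0 is None:
        z0 = Z0_SUBSET if spec.subset is not None else Z0_GLOBAL
    observed = float(count_motifs(g, spec))
    expected = expected_motif_mean(model, spec)
    analytic_std = expected_motif_std(model, spec)
    if analytic_std is not None:
        std, source = analytic_std, "analytic"
    else:
        smp = sample(model, n_draws=n_draws, seed=seed, observables=[spec])
        (_, std_arr) = sampling_moments(smp, f"motif_{spec.name}")
        std, source = float(std_arr), "sampled"
    z = _safe_z(observed, expected, std)
    s = (observed - expected) / expected if expected != 0 else math.nan
    cv = std / expected if expected != 0 else math.nan
    return MotifReport(
        motif=spec.name,
        observed=observed,
        expected=expected,
        std=std,
        z_score=z,
        similarity=s,
        cv=cv,
        z0=z0,
        significant=math.isfinite(z) and abs(z) > z0,
        moment_source=source,
    )


@dataclass(frozen=True)
class DistributionSummary:
    """Shape diagnostics of one observable's ensemble distribution."""

    observable: str
    n_draws: int
    skewness: float
    excess_kurtosis: float
    normality_stat: float
    normality_pvalue: float
    degenerate: bool

    def to_dict(self) -> dict:
        return {
            "observable": self.observable,
            "n_draws": self.n_draws,
            "skewness": self.skewness,
            "excess_kurtosis": self.excess_kurtosis,
            "normality_stat": self.normality_stat,
            "normality_pvalue": self.normality_pvalue,
            "degenerate": self.degenerate,
        }


def distribution_summary(s: EnsembleSample, observable: str) -> DistributionSummary:
    """Skewness, excess kurtosis and a D'Agostino omnibus normality test.

    Supports the gaussian reading of z-scores: if the ensemble
    distribution of the observable is near-normal, a z-score is a proper
    standardized variable.  Constant draws are flagged degenerate.
    """
    if observable not in s.draws:
        raise KeyError(f"observable {observable!r} was not requested at sampling time")
    values = np.asarray(s.draws[observable], dtype=float)
    if values.ndim != 1:
        raise ValueError("distribution summary is defined for scalar observables")
    values = values[~np.isnan(values)]
    if values.size < 100:
        raise ValueError("at least 100 draws required for distribution diagnostics")
    if np.ptp(values) == 0:
        return DistributionSummary(
            observable=observable,
            n_draws=int(values.size),
            skewness=math.nan,
            excess_kurtosis=math.nan,
            normality_stat=math.nan,
            normality_pvalue=math.nan,
            degenerate=True,
        )
    stat, pvalue = stats.normaltest(values)
    return DistributionSummary(
        observable=observable,
        n_draws=int(values.size),
        skewness=float(stats.skew(values)),
        excess_kurtosis=float(stats.kurtosis(values)),
        normality_stat=float(stat),
        normality_pvalue=float(pvalue),
        degenerate=False,
    )


@dataclass(frozen=True)
class ObservableReport:
    """Observed vs ensemble statistics for the full observable battery."""

    scalars: dict
    per_node: dict
    n_draws: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "scalars": self.scalars,
            "per_node": self.per_node,
            "n_draws": self.n_draws,
            "seed": self.seed,
        }


def _scalar_entry(observed: float, mean: float, std: float) -> dict:
    return {
        "observed": observed,
        "expected": mean,
        "std": std,
        "z_score": _safe_z(observed, mean, std) if not math.isnan(observed) else math.nan,
    }


def _band_entry(labels: Sequence[str], observed: np.ndarray, mean: np.ndarray, std: np.ndarray) -> dict:
    return {
        str(lab): {
            "observed": float(observed[i]),
            "expected": float(mean[i]),
            "std": float(std[i]),
            "band1": [float(mean[i] - std[i]), float(mean[i] + std[i])],
            "band2": [float(mean[i] - 2 * std[i]), float(mean[i] + 2 * std[i])],
        }
        for i, lab in enumerate(labels)
    }


def observable_report(
    g: BipartiteGraph,
    model: Model,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
    include_fitness: bool = True,
) -> ObservableReport:
    """Observed value, ensemble mean/std and z-score for the full battery:
    per-node ANPU/ANCD (with ±1σ/±2σ bands), their layer means, the
    assortativity coefficient, NODF components and — optionally — the
    rank-averaged fitness/complexity curves.

    Fitness and complexity ensemble curves are averaged over *ranked*
    nodes (per draw, defined values sorted descending), not node
    identities: the node ranked first differs between draws, so the rank
    curve, not the identity curve, is the reproducible object.
    """
    from bicmkit.observables import assortativity_profile

    obs_specs: list[ObservableSpec] = [
        "anpu",
        "ancd",
        "mean_anpu",
        "mean_ancd",
        "assortativity_r",
        "nodf_total",
        "nodf_rows",
        "nodf_cols",
    ]
    if include_fitness:
        obs_specs += ["fitness_ranked", "complexity_ranked"]
    smp = sample(model, n_draws=n_draws, seed=seed, observables=obs_specs)

    prof = assortativity_profile(g)
    observed_nodf = nodf(g)
    r_obs = assortativity_coefficient(g)

    scalars: dict = {}
    for name, observed in [
        ("mean_anpu", prof.mean_anpu),
        ("mean_ancd", prof.mean_ancd),
        ("assortativity_r", math.nan if r_obs is None else r_obs),
        ("nodf_total", observed_nodf.nodf_total),
        ("nodf_rows", observed_nodf.nodf_rows),
        ("nodf_cols", observed_nodf.nodf_cols),
    ]:
        mean, std = sampling_moments(smp, name)
        scalars[name] = _scalar_entry(float(observed), float(mean), float(std))
    scalars["mean_anpu"]["ci95_observed"] = list(prof.ci95_anpu)
    scalars["mean_ancd"]["ci95_observed"] = list(prof.ci95_ancd)

    per_node: dict = {}
    for name, labels, observed in [
        ("anpu", g.row_labels, prof.anpu),
        ("ancd", g.col_labels, prof.ancd),
    ]:
        mean, std = sampling_moments(smp, name)
        per_node[name] = _band_entry(labels, observed, mean, std)

    if include_fitness:
        fc = fitness_complexity(g)
        for name, labels, observed in [
            ("fitness_ranked", g.row_labels, _ranked(fc.fitness, g.n_rows)),
            ("complexity_ranked", g.col_labels, _ranked(fc.complexity, g.n_cols)),
        ]:
            mean, std = sampling_moments(smp, name)
            ranks = [f"rank{i + 1}" for i in range(len(observed))]
            per_node[name] = _band_entry(ranks, observed, mean, std)

    return ObservableReport(
        scalars=scalars, per_node=per_node, n_draws=n_draws, seed=int(seed)
    )
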