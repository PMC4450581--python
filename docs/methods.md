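# Methods

## The model

`bicmkit` works on binary, undirected bipartite networks: a 0/1
biadjacency matrix **M** of shape C × P linking a "row" layer (countries,
pollinators, species) to a "column" layer (products, plants, sites). The
null model at the core of the package is the **bipartite configuration
model (BiCM)**: the maximum-entropy probability distribution over all
2^(C·P) binary matrices whose *expected* row and column degree sequences
equal the observed ones. Constrained entropy maximization gives an
exponential family in which every pair (c, p) carries an independent
Bernoulli link with probability

    p_cp = x_c y_p / (1 + x_c y_p),

one hidden variable per node (the exponentiated Lagrange multiplier of
its degree constraint). The hidden variables are the maximizers of the
log-likelihood of the observed matrix,

    LL(x, y) = Σ_c d_c ln x_c + Σ_p u_p ln y_p − Σ_{c,p} ln(1 + x_c y_p),

whose stationarity conditions are exactly the C + P constraint equations
⟨d_c⟩ = d_c, ⟨u_p⟩ = u_p. The **bipartite random graph (BiRG)** is the
single-constraint special case, p = L/(C·P) for every pair.

Because the measure factorizes over pairs, most expectations are
analytic. The count of order-n co-occurrence motifs through one column
(V-motifs: n-tuples of rows sharing that column) is binom(S, 2) of a
Poisson-binomial sum, so its expectation is the n-th elementary symmetric
polynomial e_n of that column's link probabilities, summed over columns
(Λ-motifs mirror over rows). For n ≤ 2 the variance is also closed-form
via factorial moments, E[(S)_k] = k!·e_k and
[(S)_2]² = (S)_4 + 4(S)_3 + 2(S)_2, giving per column

    Var = 6 e_4 + 6 e_3 + e_2 − e_2²,

with columns independent so variances add. For n ≥ 3 only the mean is
computed analytically; the standard deviation comes from ensemble
sampling and the report flags `moment_source="sampled"`. (Exact closed
forms for higher orders exist but are deliberately left as a seam: the
sampled estimate is unbiased and the flag keeps the provenance honest.)

An observable X with observed value X*, ensemble mean ⟨X⟩ and standard
deviation σ is scored by the z-score z = (X* − ⟨X⟩)/σ and the similarity
s = (X* − ⟨X⟩)/⟨X⟩; their ratio s/z = σ/⟨X⟩ is the ensemble coefficient
of variation. Default significance thresholds are |z| > 1.65 for the
aggregated Vn/Λn families and |z| > 2 for subset-restricted motifs.
Motif abundances are sums of many weakly dependent indicators and their
ensemble distributions are near-gaussian, which is what gives the z-score
its probabilistic reading; `distribution_summary` (skewness, excess
kurtosis, D'Agostino omnibus test) lets a user check this on their own
matrix rather than assume it.

The normalized Shannon entropy of the ensemble,
S = −(1/(C·P)) Σ_cp [p ln p + (1−p) ln(1−p)] ≤ ln 2, quantifies how much
uncertainty each constraint set removes; the BiCM entropy never exceeds
the BiRG entropy for the same matrix, since it adds constraints.

## Solver

The likelihood system is solved on **degree equivalence classes**: nodes
with identical degree provably share a hidden variable, so the unknowns
reduce to (distinct row degrees) + (distinct column degrees). The solver
iterates the fixed point

    x_i ← d_i / Σ_j n_j y_j / (1 + x_i y_j)

(and symmetrically for y), initialized at x_i = d_i/√L, until the worst
degree residual falls below `tol` (default 1e−8, `max_iter` 5000). If the
fixed point stalls, a Levenberg–Marquardt root find on log-parameters
(positivity-preserving) finishes the job; failure to reach tolerance
raises with the residual trace attached. The fit is deterministic and
independent of node ordering.

Degenerate degrees get the exact multiplier limits instead of a numeric
solve: a zero-degree node forces p = 0 on its line, a saturated node
(degree equal to the opposite layer's size) forces p = 1. Saturation is
peeled *iteratively* — removing a full line can saturate or empty further
nodes — so a matrix whose degree sequence admits a single realization
(e.g. a perfect staircase) collapses to a deterministic ensemble with
p ∈ {0,1}, probability 1 on the observed matrix, and all z-scores zero.
Both limits satisfy their constraint equations exactly.

## Observables on a single matrix

* **ANPU / ANCD** (average nearest-neighbor degrees across layers):
  anpu_c = Σ_p m_cp u_p / d_c, ancd_p = Σ_c m_cp d_c / u_p. Zero-degree
  nodes are undefined (NaN) and excluded from layer means; if a whole
  layer is empty the mean raises. Means carry normal-approximation 95%
  CIs (mean ± 1.96·sd/√n over defined entries — the simplest standard
  construction; nothing here depends on a more elaborate interval). Since
  anpu counts a row's average number of competitors per neighbor, mean
  ANPU ∈ [0, C] and `globalization_index = mean_anpu / C` ∈ [0, 1];
  symmetrically `homogeneity_index = mean_ancd / P`.
* **Assortativity coefficient r**: Pearson correlation of endpoint
  degrees (d_c, u_p) across links. In a bipartite graph each link has one
  endpoint per layer, so the "remaining degree" (degree − 1) variant
  differs by an affine shift and gives the identical correlation; raw
  degrees are used. Degenerate cases (under two links, or zero degree
  variance on a side, as in biregular/complete graphs) return `None`
  rather than a number.
* **NODF nestedness** (0–100): for each unordered node pair within a
  layer with strictly decreasing positive degrees, the paired overlap is
  100·|N_i ∩ N_j|/d_j; equal or zero degrees contribute 0
  (decreasing-fill condition). Per-layer components average over all
  pairs of that layer; the total pools both layers' pair sums. The
  measure is permutation-invariant because the condition compares
  marginal totals, not positions. Verified exactly against the
  independent `vegan::nestednodf` implementation in R.
* **Fitness–complexity**: the coupled iteration F̃_c = Σ_p m_cp Q_p,
  Q̃_p = 1/Σ_c m_cp/F_c, each vector renormalized to unit mean per step,
  from all-ones, until the max relative change < `tol` (1e−8) or
  `max_iter` (1000). The map is known not to converge on some matrices
  (extremal fitness values can decay geometrically toward 0); the result
  carries `converged`, the iteration count and the full change trace, and
  rankings are typically stable long before numerical convergence.
  Zero-degree nodes are excluded (NaN) — they would divide by zero.
  `rank_by_fitness` reorders rows by decreasing fitness and columns by
  increasing complexity, the ordering that exposes the triangular shape.

## Ensemble sampling

A draw is C·P independent coin flips against the link-probability
matrix. Draw i uses the RNG substream `SeedSequence((seed, i))`, so runs
are bit-reproducible, prefixes are stable when `n_draws` grows, and the
observable list can be extended without changing earlier draws. Draws are
reduced on the fly (constant memory); matrices are kept only under
`keep_matrices=True`. Fitness/complexity ensemble curves are averaged
over *ranked* nodes per draw — the identity of the top-ranked node varies
across the ensemble, so the rank curve is the reproducible object — using
a relaxed per-draw iteration budget (tol 1e−7, 300 iterations) since only
the sorted values enter.

## Synthetic fixtures

The generator provides the study conditions for all tests:

* `hidden_variable` — lognormal(0, σ²) hidden variables on both layers
  (σ = 1 by default), rescaled by bisection so the expected connectance
  hits a target (0.1 by default: sparse, heavy-tailed degree sequences of
  the kind real incidence matrices show). This realizes the factorized
  measure itself, so refitting recovers the generating probabilities — the
  parameter-recovery check.
* `nested` — triangular fill: row i links the first
  round(2·fill·P·((C−i)/C)^shape) columns (fill = 0.5, shape = 1 by
  default; shape > 1 curves the boundary), then each link is *deleted*
  with probability `noise` (default 0), except every row's first link.
  Deletion noise thins baskets without ever attaching low-degree rows to
  rare columns, so observed matrices stay maximally disassortative for
  their degree sequences — the property that makes the fixture reproduce
  the qualitative real-data pattern (null ⟨r⟩ negative but closer to zero
  than observed r, NODF well reproduced). Symmetric flip noise was
  rejected for exactly this reason: corner links between low-degree rows
  and rare columns invert the comparison.
* `biregular`, `random_uniform` — exact edge cases (uniform solution,
  BiRG measure).

What the fixtures do *not* emulate: temporal correlation across
snapshots, the curved "beak" of empirical complexity profiles, or any
economic/ecological covariates. Passing tests show the machinery is
correct and that the qualitative null-model phenomenology appears under
realistic degree heterogeneity — not that any particular empirical
dataset behaves this way.

## Numerical choices and edge cases

* Degree residual tolerance 1e−8; class-reduced fixed point handles the
  full 151 × 538 trade-web shape in milliseconds.
* Elementary symmetric polynomials use the stable add-one-item
  recurrence; all arguments are probabilities in [0, 1] so no
  cancellation occurs.
* z-scores treat a standard deviation below 1e−12·(1+|mean|) as zero
  (accumulation roundoff on degenerate ensembles), returning 0 when the
  observation matches the mean and a signed infinity sentinel otherwise.
  log-probabilities return −inf when a matrix contradicts a hard 0/1 in
  the model.
* Dense loader coerces any strictly positive cell to 1 with a warning
  (inputs are expected to be pre-thresholded); duplicate edge-list rows
  collapse; isolated nodes are kept, with NaN for observables undefined
  on them.
* Rectangularity uses the sign-free form R = |P − C|/(P + C) ∈ [0, 1):
  the sign would depend on the arbitrary ordering of the layers.
* Similarity is s = (X* − ⟨X⟩)/⟨X⟩, the unique normalization consistent
  with s/z equalling the coefficient of variation; it is NaN when
  ⟨X⟩ = 0.

## Problem sizes used in the checks

Enumeration oracles run on 2×2 and 2×3 ensembles (every matrix, every
achievable degree sequence); constraint satisfaction on 50
hidden-variable fixtures with random shapes up to 151 × 538; sampling
fidelity on 10⁵ draws of a 2×2 model plus a root-n convergence sweep to
16384 draws; parameter recovery at 60 × 200; the qualitative
assortativity/nestedness comparison on a 60 × 180 nested fixture
(shape 2, noise 0.1) with 2000 draws. These sizes make the full battery
run in well under a minute while keeping every statistical check
comfortably powered.

## Known limitations

* Motif standard deviations for orders ≥ 3 are sampled, not closed-form.
* Higher-order motif families that tuple *both* layers simultaneously
  (beyond Vn/Λn) are not implemented.
* The fitness–complexity map's non-convergence on degenerate matrices is
  reported, not resolved; rank-stable output is the supported contract.
* Only binary, undirected bipartite networks are supported — no weights,
  no direction, no microcanonical (exact-degree) randomization.
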