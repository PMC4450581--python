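import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from bicmkit import (
    BipartiteGraph,
    MotifSpec,
    assortativity_coefficient,
    assortativity_profile,
    count_motifs,
    fitness_complexity,
    nodf,
    project,
    rank_by_fitness,
)

matrices = arrays(
    dtype=np.int8,
    shape=st.tuples(st.integers(2, 8), st.integers(2, 8)),
    elements=st.integers(0, 1),
)


# ---------------------------------------------------------------------------
# ANPU / ANCD
# ---------------------------------------------------------------------------

class TestAssortativityProfile:
    def test_toy_values(self, toy):
        prof = assortativity_profile(toy)
        assert prof.anpu.tolist() == [1.5, 2.0]
        assert prof.ancd[:2].tolist() == [1.5, 2.0]
        assert np.isnan(prof.ancd[2])  # isolated product
        assert prof.mean_anpu == pytest.approx(1.75)
        assert prof.mean_ancd == pytest.approx(1.75)

    def test_complete_graph(self):
        g = BipartiteGraph.from_matrix(np.ones((3, 4), dtype=int))
        prof = assortativity_profile(g)
        assert np.allclose(prof.anpu, 3.0)  # every product has full ubiquity
        assert np.allclose(prof.ancd, 4.0)  # every country has full diversification
        assert prof.globalization_index == pytest.approx(1.0)
        assert prof.homogeneity_index == pytest.approx(1.0)

    def test_empty_layer_is_an_error(self):
        g = BipartiteGraph.from_matrix(np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError, match="degree zero"):
            assortativity_profile(g)

    @given(matrices)
    def test_bounds(self, m):
        if m.sum() == 0:
            return
        g = BipartiteGraph.from_matrix(m)
        prof = assortativity_profile(g)
        anpu = prof.anpu[~np.isnan(prof.anpu)]
        ancd = prof.ancd[~np.isnan(prof.ancd)]
        assert ((anpu >= 1) & (anpu <= g.n_rows)).all()
        assert ((ancd >= 1) & (ancd <= g.n_cols)).all()
        assert 0.0 <= prof.globalization_index <= 1.0
        assert 0.0 <= prof.homogeneity_index <= 1.0


# ---------------------------------------------------------------------------
# Motifs
# ---------------------------------------------------------------------------

class TestMotifs:
    @pytest.mark.parametrize(
        "family,order,expected",
        [("V", 2, 1), ("Lambda", 2, 1), ("V", 3, 0), ("V", 1, 3), ("Lambda", 1, 3)],
    )
    def test_toy_counts(self, toy, family, order, expected):
        assert count_motifs(toy, MotifSpec(family, order)) == expected

    def test_disjoint_baskets(self):
        g = BipartiteGraph.from_matrix(np.array([[1, 1, 0, 0], [0, 0, 1, 1]]))
        assert count_motifs(g, MotifSpec("V", 2)) == 0

    def test_subset_restriction(self):
        # three rows; restricting V2 to the first two ignores the third's links
        m = np.array([[1, 1], [1, 1], [1, 1]])
        g = BipartiteGraph.from_matrix(m, ["a", "b", "c"], ["p", "q"])
        assert count_motifs(g, MotifSpec("V", 2)) == 2 * 3  # binom(3,2) per column
        assert count_motifs(g, MotifSpec("V", 2, subset=("a", "b"))) == 2
        assert count_motifs(g, MotifSpec("V", 1, subset=("a",))) == 2

    def test_unknown_subset_label(self, toy):
        with pytest.raises(KeyError):
            count_motifs(toy, MotifSpec("V", 2, subset=("nope",)))

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            MotifSpec("V", 0)
        with pytest.raises(ValueError):
            MotifSpec("W", 2)

    @given(matrices)
    def test_order_one_equals_links_both_families(self, m):
        g = BipartiteGraph.from_matrix(m)
        L = g.n_links
        assert count_motifs(g, MotifSpec("V", 1)) == L
        assert count_motifs(g, MotifSpec("Lambda", 1)) == L

    @given(matrices)
    def test_v2_matches_projection_cross_check(self, m):
        g = BipartiteGraph.from_matrix(m)
        w = project(g, "rows").weights
        off_diag_pairs = (w.sum() - np.trace(w)) // 2
        assert count_motifs(g, MotifSpec("V", 2)) == off_diag_pairs

    @given(matrices)
    def test_counts_vanish_beyond_max_degree(self, m):
        g = BipartiteGraph.from_matrix(m)
        for family, degrees in (("V", g.col_degrees), ("Lambda", g.row_degrees)):
            kmax = int(degrees.max(initial=0))
            assert count_motifs(g, MotifSpec(family, kmax + 1)) == 0
            if kmax >= 1:
                assert count_motifs(g, MotifSpec(family, kmax)) >= 1


# ---------------------------------------------------------------------------
# Assortativity coefficient
# ---------------------------------------------------------------------------

class TestAssortativityCoefficient:
    def test_block_diagonal_is_assortative(self):
        g = BipartiteGraph.from_matrix(
            np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]])
        )
        r = assortativity_coefficient(g)
        assert r is not None and r > 0

    def test_complete_graph_undefined(self):
        g = BipartiteGraph.from_matrix(np.ones((3, 3), dtype=int))
        assert assortativity_coefficient(g) is None

    def test_nested_star(self):
        g = BipartiteGraph.from_matrix(np.array([[1, 1], [1, 0]]))
        assert assortativity_coefficient(g) == pytest.approx(-0.5)

    @given(matrices)
    def test_range(self, m):
        r = assortativity_coefficient(BipartiteGraph.from_matrix(m))
        if r is not None:
            assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# NODF
# ---------------------------------------------------------------------------

class TestNodf:
    def test_perfectly_nested(self, nested3):
        res = nodf(nested3)
        assert res.nodf_total == pytest.approx(100.0)
        assert res.nodf_rows == pytest.approx(100.0)
        assert res.nodf_cols == pytest.approx(100.0)

    def test_checkerboard(self):
        res = nodf(BipartiteGraph.from_matrix(np.eye(2, dtype=int)))
        assert res.nodf_total == 0.0

    def test_equal_degrees_contribute_zero(self):
        res = nodf(BipartiteGraph.from_matrix(np.ones((2, 2), dtype=int)))
        assert res.nodf_total == 0.0

    def test_total_is_pair_weighted_combination(self):
        rng = np.random.default_rng(5)
        m = (rng.random((6, 9)) < 0.4).astype(int)
        res = nodf(BipartiteGraph.from_matrix(m))
        rp, cp = 6 * 5 // 2, 9 * 8 // 2
        combined = (res.nodf_rows * rp + res.nodf_cols * cp) / (rp + cp)
        assert res.nodf_total == pytest.approx(combined)

    def test_against_vegan_oracle(self):
        """Independent oracle: R vegan::nestednodf on a fixed 5x7 matrix."""
        m = np.array(
            [
                [0, 1, 0, 0, 1, 0, 0],
                [0, 1, 0, 1, 0, 0, 0],
                [0, 1, 1, 1, 1, 0, 0],
                [1, 1, 0, 0, 0, 1, 0],
                [0, 0, 1, 1, 0, 0, 1],
            ]
        )
        res = nodf(BipartiteGraph.from_matrix(m))
        # values frozen from vegan 2.7 (nestednodf(m, order=TRUE, weighted=FALSE))
        assert res.nodf_rows == pytest.approx(45.0, abs=1e-4)
        assert res.nodf_cols == pytest.approx(36.50794, abs=1e-4)
        assert res.nodf_total == pytest.approx(39.24731, abs=1e-4)
        # and live, in case the frozen values ever drift from the oracle
        script = textwrap.dedent(
            """
            suppressMessages(library(vegan))
            m <- matrix(c(%s), nrow=5, byrow=TRUE)
            cat(sprintf("%%.10f", nestednodf(m, order=TRUE, weighted=FALSE)$statistic), sep="\\n")
            """
            % ",".join(str(v) for v in m.ravel())
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert proc.returncode == 0, proc.stderr
        ncol_r, nrow_r, total_r = (float(v) for v in proc.stdout.split())
        assert res.nodf_rows == pytest.approx(nrow_r, abs=1e-6)
        assert res.nodf_cols == pytest.approx(ncol_r, abs=1e-6)
        assert res.nodf_total == pytest.approx(total_r, abs=1e-6)

    @given(matrices, st.randoms(use_true_random=False))
    def test_permutation_invariance(self, m, rnd):
        rows = list(range(m.shape[0]))
        cols = list(range(m.shape[1]))
        rnd.shuffle(rows)
        rnd.shuffle(cols)
        a = nodf(BipartiteGraph.from_matrix(m))
        b = nodf(BipartiteGraph.from_matrix(m[np.ix_(rows, cols)]))
        assert a.nodf_total == pytest.approx(b.nodf_total)
        assert a.nodf_rows == pytest.approx(b.nodf_rows)
        assert a.nodf_cols == pytest.approx(b.nodf_cols)


# ---------------------------------------------------------------------------
# Fitness / complexity
# ---------------------------------------------------------------------------

class TestFitnessComplexity:
    def test_complete_matrix_fixed_point(self):
        g = BipartiteGraph.from_matrix(np.ones((3, 4), dtype=int))
        fc = fitness_complexity(g)
        assert fc.converged
        assert fc.n_iterations == 1
        assert np.allclose(fc.fitness, 1.0)
        assert np.allclose(fc.complexity, 1.0)

    def test_nested_ordering(self, nested3):
        fc = fitness_complexity(nested3, max_iter=2000)
        F, Q = fc.fitness, fc.complexity
        assert F[0] > F[1] > F[2]
        assert Q[2] > Q[1] > Q[0]  # rarest product is most complex

    def test_unit_mean_normalization(self):
        rng = np.random.default_rng(0)
        g = BipartiteGraph.from_matrix((rng.random((8, 12)) < 0.5).astype(int))
        fc = fitness_complexity(g)
        assert np.nanmean(fc.fitness) == pytest.approx(1.0)
        assert np.nanmean(fc.complexity) == pytest.approx(1.0)

    def test_label_equivariance_under_row_permutation(self):
        rng = np.random.default_rng(1)
        m = (rng.random((6, 10)) < 0.5).astype(int)
        m[m.sum(axis=1) == 0, 0] = 1
        perm = rng.permutation(6)
        fc1 = fitness_complexity(BipartiteGraph.from_matrix(m))
        fc2 = fitness_complexity(BipartiteGraph.from_matrix(m[perm]))
        assert np.allclose(fc1.fitness[perm], fc2.fitness, equal_nan=True)

    def test_zero_degree_nodes_reported_nan(self, toy):
        fc = fitness_complexity(toy)
        assert np.isnan(fc.complexity[2])
        assert np.isfinite(fc.fitness).all()

    def test_empty_graph_raises(self):
        g = BipartiteGraph.from_matrix(np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError):
            fitness_complexity(g)

    def test_nonconvergence_is_flagged_not_raised(self):
        g = BipartiteGraph.from_matrix(np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]]))
        fc = fitness_complexity(g, tol=1e-12, max_iter=5)
        assert not fc.converged
        assert fc.n_iterations == 5
        assert fc.trace.shape == (5,)


class TestRankByFitness:
    def test_idempotent_on_ordered_matrix(self, nested3):
        out = rank_by_fitness(nested3)
        assert np.array_equal(out.matrix, nested3.matrix)

    def test_restores_nested_order_after_reversal(self, nested3):
        reversed_g = BipartiteGraph.from_matrix(
            nested3.matrix[::-1], ["r2", "r1", "r0"], nested3.col_labels
        )
        out = rank_by_fitness(reversed_g)
        assert np.array_equal(out.matrix, nested3.matrix)
        assert out.row_labels == ("r0", "r1", "r2")

    def test_nodf_invariant_under_ranking(self):
        rng = np.random.default_rng(2)
        m = (rng.random((7, 11)) < 0.45).astype(int)
        m[m.sum(axis=1) == 0, 0] = 1
        m[0, m.sum(axis=0) == 0] = 1
        g = BipartiteGraph.from_matrix(m)
        assert nodf(rank_by_fitness(g)).nodf_total == pytest.approx(
            nodf(g).nodf_total
        )
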