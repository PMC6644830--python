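import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locimap.engine import MappingTable
from locimap.metrics import (
    CallResult,
    call_conformation,
    contour_accuracy,
    edit_distance,
    entropy,
    quality_report,
    unrecovered_information,
)
from locimap.polymer import MISSING


def table_of(rows):
    return MappingTable(np.asarray(rows, dtype=float))


class TestUnrecoveredInformation:
    def test_perfect_reconstruction_zero(self):
        t = table_of([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        i_bits, excl = unrecovered_information(t, np.array([0, 1]))
        assert i_bits == 0.0
        assert excl == []

    def test_uniform_four_candidates_two_bits(self):
        t = table_of([[0.25, 0.25, 0.25, 0.25]])
        i_bits, _ = unrecovered_information(t, np.array([2]))
        assert i_bits == pytest.approx(2.0)

    def test_true_missing_scored_on_missing_column(self):
        t = table_of([[0.25, 0.75]])  # one spot + missing column
        i_bits, _ = unrecovered_information(t, np.array([MISSING]))
        assert i_bits == pytest.approx(-np.log2(0.75))

    def test_zero_probability_truth(self):
        t = table_of([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        i_inf, excl = unrecovered_information(t, np.array([1, MISSING]))
        assert np.isinf(i_inf)
        assert excl == [0]
        i_ex, excl2 = unrecovered_information(t, np.array([1, MISSING]),
                                              exclude_zero=True)
        assert i_ex == 0.0
        assert excl2 == [0]


class TestEntropy:
    def test_deterministic_zero(self):
        assert entropy(table_of([[1.0, 0.0], [0.0, 1.0]])) == 0.0

    def test_uniform_two_options_one_bit(self):
        assert entropy(table_of([[0.5, 0.5]])) == pytest.approx(1.0)

    def test_mean_over_loci(self):
        t = table_of([[0.5, 0.5, 0.0], [1.0, 0.0, 0.0]])
        assert entropy(t) == pytest.approx(0.5)

    def test_invariant_to_spot_relabeling(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(6), size=5)
        t = table_of(p)
        perm = rng.permutation(5)  # permute spot columns, keep missing last
        t2 = table_of(np.column_stack([p[:, :5][:, perm], p[:, 5]]))
        assert entropy(t2) == pytest.approx(entropy(t))
        truth = np.array([0, 1, 2, MISSING, 4])
        inv = np.empty(5, dtype=int)
        inv[perm] = np.arange(5)
        truth2 = np.where(truth == MISSING, MISSING, inv[np.maximum(truth, 0)])
        i1, _ = unrecovered_information(t, truth)
        i2, _ = unrecovered_information(t2, truth2)
        assert i1 == pytest.approx(i2)


class TestCaller:
    def test_near_deterministic_recovery(self):
        t = table_of([[0.97, 0.01, 0.01, 0.01],
                      [0.01, 0.97, 0.01, 0.01],
                      [0.01, 0.01, 0.97, 0.01]])
        res = call_conformation(t)
        assert res.assignment.tolist() == [0, 1, 2]

    def test_missing_mass_rule(self):
        # missing mass 0.6 beats best spot 0.3
        t = table_of([[0.3, 0.1, 0.6]])
        assert call_conformation(t).assignment.tolist() == [MISSING]

    def test_conflict_resolution_higher_wins(self):
        # both loci prefer spot 0; locus 0 wins, locus 1 takes spot 1
        t = table_of([[0.8, 0.15, 0.05],
                      [0.6, 0.35, 0.05]])
        res = call_conformation(t)
        assert res.assignment.tolist() == [0, 1]

    def test_displaced_locus_goes_missing(self):
        # loser's remaining mass is mostly missing once spot 0 is taken
        t = table_of([[0.9, 0.02, 0.08],
                      [0.55, 0.05, 0.40]])
        res = call_conformation(t)
        assert res.assignment.tolist() == [0, MISSING]

    def test_injective_output(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.dirichlet(np.ones(7), size=6)
            res = call_conformation(table_of(p))
            spots = res.assignment[res.assignment != MISSING]
            assert len(spots) == len(np.unique(spots))

    def test_matches_exhaustive_on_tiny_tables(self):
        # greedy equals the best injective assignment by product of
        # probabilities on tables with a dominant diagonal
        import itertools
        rng = np.random.default_rng(2)
        for _ in range(10):
            p = rng.dirichlet(np.ones(4) * 0.3, size=3)
            p = (p + 2.0 * np.eye(3, 4)) / (p + 2.0 * np.eye(3, 4)).sum(1, keepdims=True)
            res = call_conformation(table_of(p))
            best, best_w = None, -1.0
            for combo in itertools.product([0, 1, 2, MISSING], repeat=3):
                spots = [s for s in combo if s != MISSING]
                if len(spots) != len(set(spots)):
                    continue
                w = np.prod([p[i, s if s != MISSING else 3]
                             for i, s in enumerate(combo)])
                if w > best_w:
                    best, best_w = combo, w
            assert res.assignment.tolist() == list(best)


class TestEditDistance:
    def test_identity(self):
        assert edit_distance([1, 2, 3], [1, 2, 3]) == 0

    def test_single_indel(self):
        assert edit_distance([1, 2, 3], [1, 3]) == 1

    def test_substitution(self):
        assert edit_distance([1, 2, 3], [1, 9, 3]) == 1

    def test_empty(self):
        assert edit_distance([], []) == 0
        assert edit_distance([1, 2], []) == 2

    @given(st.lists(st.integers(0, 5), max_size=8),
           st.lists(st.integers(0, 5), max_size=8))
    @settings(max_examples=60, deadline=None)
    def test_against_recursive_oracle(self, a, b):
        import functools

        @functools.lru_cache(maxsize=None)
        def lev(x, y):
            if not x:
                return len(y)
            if not y:
                return len(x)
            return min(
                lev(x[1:], y) + 1,
                lev(x, y[1:]) + 1,
                lev(x[1:], y[1:]) + (x[0] != y[0]),
            )

        assert edit_distance(a, b) == lev(tuple(a), tuple(b))


class TestContourAccuracy:
    def test_identical(self):
        truth = np.array([3, 1, 4, MISSING, 5])
        res = contour_accuracy(CallResult(truth.copy()), truth)
        assert res.n_alignment_errors == 0
        assert res.accuracy == 1.0

    def test_looping_out_one_indel(self):
        truth = np.array([3, 1, 4, 5])
        called = np.array([3, 1, MISSING, 5])  # spot 4 skipped: looped out
        res = contour_accuracy(CallResult(called), truth)
        assert res.n_alignment_errors == 1
        assert res.accuracy == pytest.approx(0.75)

    def test_both_empty(self):
        res = contour_accuracy(CallResult(np.array([MISSING, MISSING])),
                               np.array([MISSING, MISSING]))
        assert res.accuracy == 1.0

    def test_random_permutation_mostly_errors(self):
        rng = np.random.default_rng(3)
        truth = np.arange(20)
        called = rng.permutation(20)
        res = contour_accuracy(CallResult(called), truth)
        assert res.n_alignment_errors >= 12


class TestQualityReport:
    def test_report_fields(self):
        t = table_of([[0.5, 0.25, 0.25], [0.1, 0.8, 0.1]])
        rep = quality_report(t, np.array([0, 1]))
        assert rep.n_loci == 2
        assert rep.unrecovered_bits == pytest.approx(
            (-np.log2(0.5) - np.log2(0.8)) / 2
        )
        assert rep.entropy_bits > 0
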