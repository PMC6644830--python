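import numpy as np
import pytest

from locimap import engine, oracle
from locimap.engine import (
    SERIES1,
    SERIES2,
    IllegalConstraint,
    baseline_uncertainty,
    color_uniform_table,
    evaluate_term,
    mapping_probabilities,
    missing_rate_targets,
)

from .conftest import make_spec, toy_batch


class TestTrivialPartitions:
    def test_one_locus_one_spot(self, unit_spec):
        est = evaluate_term(unit_spec)
        assert np.exp(est.log_Z) == pytest.approx(2.0)  # mapped + missing
        table = mapping_probabilities(est)
        np.testing.assert_allclose(table.probs, [[0.5, 0.5]])

    def test_two_adjacent_loci_one_spot(self):
        # (s,-), (-,s), (-,-) counted; (s,s) excluded by adjacency
        spec = make_spec([0.0, 1000.0], [0, 0], [[0.0, 0.0, 0.0]], [0], 1)
        est = evaluate_term(spec)
        assert np.exp(est.log_Z) == pytest.approx(3.0)

    def test_forward_backward_agree(self):
        for seed, spec, _ in toy_batch(range(1, 8)):
            est = evaluate_term(spec)
            assert est.log_Z == pytest.approx(est.log_Z_backward, abs=1e-8)

    def test_small_instances_match_oracle(self):
        # instances with no same-color non-adjacent locus pair cannot
        # overlap, so Z~0 is exact there
        rng = np.random.default_rng(0)
        color_patterns = {1: [0], 2: [0, 1], 3: [0, 0, 1]}
        for _ in range(10):
            n = int(rng.integers(1, 4))
            kb = np.sort(rng.uniform(0, 3000, n))
            kb += np.arange(n)  # ensure strictly increasing
            xyz = rng.uniform(0, 2000, (3, 3))
            spec = make_spec(kb, color_patterns[n], xyz,
                             rng.integers(0, 2, 3), 2,
                             q=rng.uniform(0.5, 2, 3),
                             q_miss=rng.uniform(1e-10, 1e-8, 2))
            est = evaluate_term(spec)
            ex = oracle.enumerate_partition(spec)
            assert est.log_Z == pytest.approx(ex.log_Z, abs=1e-9)


class TestMappingProbabilities:
    def test_row_sums_random_instances(self):
        for seed, spec, _ in toy_batch(range(1, 10)):
            table = mapping_probabilities(evaluate_term(spec))
            np.testing.assert_allclose(table.row_sums(), 1.0, atol=1e-9)

    def test_color_mismatch_zero(self):
        for seed, spec, _ in toy_batch(range(1, 5)):
            table = mapping_probabilities(evaluate_term(spec))
            mismatch = spec.loci.colors[:, None] != spec.spots.colors[None, :]
            assert np.all(table.mapped[mismatch] == 0.0)

    def test_zero_term_raises(self, unit_spec):
        est = evaluate_term(
            unit_spec,
            [IllegalConstraint((0, 2), 0)] * 2,  # duplicated: overlapping
        )
        assert np.isneginf(est.log_Z)
        with pytest.raises(ValueError):
            mapping_probabilities(est)


class TestConstrainedTerms:
    def _toy(self):
        # 4 loci of one color, 2 spots; constraint (0,2) -> spot 0 is legal
        return make_spec([0, 1000, 2000, 3000], [0] * 4,
                         [[0, 0, 0], [800, 0, 0]], [0, 0], 1,
                         q_miss=[1e-9])

    def test_constraint_never_increases_term(self):
        spec = self._toy()
        base = evaluate_term(spec)
        con = IllegalConstraint((0, 2), 0)
        for mode in (SERIES1, SERIES2):
            constrained = evaluate_term(spec, [con], mode)
            assert constrained.log_Z <= base.log_Z + 1e-12

    def test_series1_stricter_than_series2(self):
        spec = self._toy()
        con = IllegalConstraint((0, 2), 0)
        z1 = evaluate_term(spec, [con], SERIES1).log_Z
        z2 = evaluate_term(spec, [con], SERIES2).log_Z
        assert z1 <= z2 + 1e-12

    def test_overlapping_constraints_zero(self):
        spec = self._toy()
        cons = [IllegalConstraint((0, 2), 0), IllegalConstraint((2,  0), 1)]
        assert np.isneginf(evaluate_term(spec, cons).log_Z)

    def test_constraint_validation(self):
        with pytest.raises(ValueError):
            IllegalConstraint((0,), 0)  # too few loci
        with pytest.raises(ValueError):
            IllegalConstraint((0, 1), 0)  # adjacent
        with pytest.raises(ValueError):
            IllegalConstraint((2, 2, 4), 0)  # duplicate

    def test_constrained_term_hand_computation(self):
        # 3 same-color loci, spots s (origin) and t; constraint (0,2)->s.
        # Locus 1 cannot use s (adjacent reuse) and cannot be missing
        # (0 and 2 would become consecutive mapped loci sharing s), so the
        # term is the single conformation s -> t -> s.
        spec = make_spec([0, 1000, 2000], [0, 0, 0],
                         [[0, 0, 0], [800, 0, 0]], [0, 0], 1)
        con = IllegalConstraint((0, 2), 0)
        est = evaluate_term(spec, [con], SERIES2)
        from locimap.dna_model import propagator
        w = propagator([800.0, 0.0, 0.0], 1000.0, spec.model) ** 2
        assert np.exp(est.log_Z) == pytest.approx(w, rel=1e-9)

    def test_constraint_with_no_middle_spot_is_zero(self):
        # same constraint but no alternative spot for the middle locus:
        # every completion violates the consecutive-mapped-overlap rule
        spec = make_spec([0, 1000, 2000], [0, 0, 0], [[0, 0, 0]], [0], 1)
        est = evaluate_term(spec, [IllegalConstraint((0, 2), 0)], SERIES2)
        assert np.isneginf(est.log_Z)


class TestBaselineUncertainty:
    def test_fifteen_spots_is_four_bits(self, model):
        xyz = np.zeros((15, 3))
        spec = make_spec([0.0], [0], xyz, [0] * 15, 1, model)
        assert baseline_uncertainty(spec) == pytest.approx(4.0)

    def test_single_candidate_one_bit(self, unit_spec):
        assert baseline_uncertainty(unit_spec) == pytest.approx(1.0)

    def test_matches_uniform_table_information(self):
        from locimap.metrics import unrecovered_information
        for seed, spec, truth in toy_batch(range(1, 5)):
            table = color_uniform_table(spec)
            i_bits, _ = unrecovered_information(table, truth.true_mapping)
            assert i_bits == pytest.approx(baseline_uncertainty(spec), abs=1e-9)


class TestMissingRateTargets:
    def test_balanced_counts(self, model):
        # M_c = N_c and no extras expected: target collapses to epsilon
        spec = make_spec([0, 1000], [0, 1], np.zeros((2, 3)), [0, 1], 2, model)
        t = missing_rate_targets(spec.loci, spec.spots, p_extra=0.0)
        np.testing.assert_allclose(t, 1e-3)

    def test_missing_spot_raises_target(self, model):
        track_kb = [0, 1000, 2000, 3000]
        spec = make_spec(track_kb, [0] * 4, np.zeros((3, 3)), [0] * 3, 1, model)
        t = missing_rate_targets(spec.loci, spec.spots, p_extra=0.0)
        assert t[0] == pytest.approx(0.25)

    def test_extras_accounted(self, model):
        # 4 loci, 4 spots, one expected extra (N * p_extra = 1): ~1 net missing
        spec = make_spec([0, 1000, 2000, 3000], [0] * 4, np.zeros((4, 3)),
                         [0] * 4, 1, model)
        t = missing_rate_targets(spec.loci, spec.spots, p_extra=0.25)
        assert t[0] == pytest.approx(1.0 / 4.0)


class TestScale:
    def test_no_overflow_at_chromosome_scale(self):
        from locimap.io import RunConfig, SimConfig, simulate_experiment
        cfg = RunConfig()
        cfg.sim = SimConfig(contour_kb=300_000.0, n_colors=20, step_kb=100.0)
        spec, truth, _ = simulate_experiment(cfg, seed=11)
        assert spec.n_loci > 200
        est = evaluate_term(spec)
        assert np.isfinite(est.log_Z)
        assert est.log_Z == pytest.approx(est.log_Z_backward, abs=1e-7)
        table = mapping_probabilities(est)
        np.testing.assert_allclose(table.row_sums(), 1.0, atol=1e-8)
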