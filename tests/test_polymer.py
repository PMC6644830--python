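import numpy as np
import pytest

from locimap.polymer import (
    MISSING,
    Conformation,
    ErrorModel,
    place_labels,
    render_image,
    simulate_wlc,
    simulate_wlc_batch,
)

N_L, L_P = 0.3, 300.0


def wlc_msd(total_kb, n_l=N_L, l_p=L_P):
    """Closed-form <R^2> of the continuous wormlike chain, nm^2."""
    P = l_p / n_l
    Lc = total_kb / n_l
    return 2 * P * Lc - 2 * P * P * (1 - np.exp(-Lc / P))


class TestSimulateWlc:
    def test_rigid_rod_limit(self):
        # L << l_p: chain is nearly straight; end-to-end close to contour
        verts = simulate_wlc_batch(N_L, L_P, 30.0, 1.0, 300, seed=0)
        r = np.linalg.norm(verts[:, -1] - verts[:, 0], axis=1)
        contour = 30.0 / N_L
        assert np.mean(r) == pytest.approx(contour, rel=0.03)
        assert np.all(r <= contour + 1e-9)

    def test_persistence_scale_end_to_end(self):
        # at L = l_p the closed form, not the rod limit, applies
        verts = simulate_wlc_batch(N_L, L_P, 300.0, 10.0, 600, seed=0)
        r2 = np.sum((verts[:, -1] - verts[:, 0]) ** 2, axis=1)
        assert np.mean(r2) == pytest.approx(wlc_msd(300.0), rel=0.1)

    def test_msd_matches_closed_form(self):
        total = 30_000.0
        verts = simulate_wlc_batch(N_L, L_P, total, 25.0, 1500, seed=1)
        r2 = np.sum((verts[:, -1] - verts[:, 0]) ** 2, axis=1)
        expected = wlc_msd(total)
        # Monte-Carlo standard error of the mean of ~chi2-like r2
        se = np.std(r2) / np.sqrt(len(r2))
        assert abs(np.mean(r2) - expected) < 4 * se + 0.02 * expected

    def test_tangent_autocorrelation(self):
        step = 20.0
        verts = simulate_wlc_batch(N_L, L_P, 6000.0, step, 400, seed=2)
        t = np.diff(verts, axis=1)
        t /= np.linalg.norm(t, axis=2, keepdims=True)
        lags = np.arange(1, 8)
        corr = [np.mean(np.sum(t[:, :-k] * t[:, k:], axis=2)) for k in lags]
        slope = np.polyfit(lags * step, np.log(corr), 1)[0]
        assert -1.0 / slope == pytest.approx(L_P, rel=0.1)

    def test_invalid_params(self):
        for kwargs in [dict(n_l=0), dict(l_p=-1), dict(step=0)]:
            with pytest.raises(ValueError):
                simulate_wlc(**{"n_l": N_L, "l_p": L_P, "total_length": 1000.0,
                                "step": 10.0, **kwargs})
        with pytest.raises(ValueError):
            simulate_wlc(N_L, L_P, total_length=5.0, step=10.0)

    def test_reproducible(self):
        a = simulate_wlc(N_L, L_P, 1000.0, 10.0, seed=42)
        b = simulate_wlc(N_L, L_P, 1000.0, 10.0, seed=42)
        assert np.array_equal(a.vertices, b.vertices)

    def test_conformation_invariants(self):
        c = simulate_wlc(N_L, L_P, 1000.0, 10.0, seed=3)
        assert len(c.vertices) == len(c.contour_positions)
        assert np.all(np.diff(c.contour_positions) > 0)


class TestConformation:
    def test_rejects_bad_shapes(self):
        with pytest.raises(ValueError):
            Conformation(np.zeros((3, 3)), np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            Conformation(np.zeros((1, 3)), np.array([0.0]))
        with pytest.raises(ValueError):
            Conformation(np.zeros((2, 3)), np.array([1.0, 1.0]))


class TestPlaceLabels:
    def test_mean_density(self):
        conf = simulate_wlc(N_L, L_P, 30_000.0, 50.0, seed=4)
        counts = [len(place_labels(conf, 1.0, 3, seed=s)[0]) for s in range(40)]
        # Poisson(30): mean within ~4 sigma/sqrt(40)
        assert abs(np.mean(counts) - 30.0) < 4 * np.sqrt(30.0 / 40)

    def test_experiment2_density(self):
        conf = simulate_wlc(N_L, L_P, 300_000.0, 100.0, seed=5)
        track, xyz = place_labels(conf, 1.0, 20, seed=5)
        assert 230 <= len(track) <= 370  # ~300 loci
        per_color = np.bincount(track.colors, minlength=20)
        assert abs(per_color.mean() - len(track) / 20) < 1e-9

    def test_zero_density_empty(self):
        conf = simulate_wlc(N_L, L_P, 10_000.0, 50.0, seed=6)
        track, xyz = place_labels(conf, 0.0, 3, seed=6)
        assert len(track) == 0

    def test_sorted_and_interpolated(self):
        conf = simulate_wlc(N_L, L_P, 10_000.0, 50.0, seed=7)
        track, xyz = place_labels(conf, 2.0, 3, seed=7)
        assert np.all(np.diff(track.genomic_kb) > 0)
        assert xyz.shape == (len(track), 3)
        # positions lie within the chain's bounding box
        assert np.all(xyz >= conf.vertices.min(axis=0) - 1e-9)
        assert np.all(xyz <= conf.vertices.max(axis=0) + 1e-9)

    def test_invalid(self):
        conf = simulate_wlc(N_L, L_P, 1000.0, 10.0, seed=8)
        with pytest.raises(ValueError):
            place_labels(conf, -1.0, 3)
        with pytest.raises(ValueError):
            place_labels(conf, 1.0, 0)


class TestRenderImage:
    def _positions(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        return rng.uniform(0, 5000, (n, 3)), rng.integers(0, 3, n)

    def test_no_error_identity(self):
        xyz, colors = self._positions()
        err = ErrorModel(0.0, 0.0, 0.0, 0.0)
        field, truth = render_image(xyz, colors, 3, err, seed=1)
        assert len(field) == len(xyz)
        assert np.all(truth.true_mapping != MISSING)
        assert truth.extra_spots.size == 0
        np.testing.assert_allclose(field.xyz[truth.true_mapping], xyz)
        assert np.array_equal(field.colors[truth.true_mapping], colors)

    def test_all_missing(self):
        xyz, colors = self._positions()
        field, truth = render_image(xyz, colors, 3,
                                    ErrorModel(0, 0, 0.999999999, 0.5), seed=2)
        assert np.all(truth.true_mapping == MISSING)
        assert len(field) == truth.extra_spots.size

    def test_missing_fraction_binomial(self):
        from scipy.stats import binomtest
        xyz, colors = self._positions(n=2000, seed=3)
        n_missing = 0
        for s in range(5):
            _, truth = render_image(xyz, colors, 3, ErrorModel(0, 0, 0.1, 0.0),
                                    seed=s)
            n_missing += int((truth.true_mapping == MISSING).sum())
        res = binomtest(n_missing, 10000, 0.1)
        assert res.pvalue > 1e-4

    def test_mapping_partition_invariant(self):
        xyz, colors = self._positions(n=100, seed=4)
        field, truth = render_image(xyz, colors, 3, ErrorModel(50, 100, 0.2, 0.3),
                                    seed=5)
        mapped = truth.true_mapping[truth.true_mapping != MISSING]
        assert len(mapped) == len(np.unique(mapped))  # injective
        assert set(mapped) | set(truth.extra_spots) == set(range(len(field)))
        assert not set(mapped) & set(truth.extra_spots)

    def test_localization_noise_scale(self):
        xyz, colors = self._positions(n=5000, seed=6)
        field, truth = render_image(xyz, colors, 3, ErrorModel(100, 200, 0, 0),
                                    seed=7)
        d = field.xyz[truth.true_mapping] - xyz
        assert np.std(d[:, 0]) == pytest.approx(100, rel=0.08)
        assert np.std(d[:, 2]) == pytest.approx(200, rel=0.08)

    def test_reproducible(self):
        xyz, colors = self._positions()
        err = ErrorModel(100, 200, 0.1, 0.1)
        f1, t1 = render_image(xyz, colors, 3, err, seed=9)
        f2, t2 = render_image(xyz, colors, 3, err, seed=9)
        assert np.array_equal(f1.xyz, f2.xyz)
        assert np.array_equal(t1.true_mapping, t2.true_mapping)

    def test_error_model_validation(self):
        with pytest.raises(ValueError):
            ErrorModel(p_fn=1.0)
        with pytest.raises(ValueError):
            ErrorModel(sigma_xy=-1.0)
        with pytest.raises(ValueError):
            ErrorModel(p_extra=-0.1)
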