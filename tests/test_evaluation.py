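"""Accuracy statistics: degree conversion, Gaussian band mass, KDE, filtering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from gazekit.evaluation import (
    DEFAULT_BAND,
    ErrorSet,
    GaussianAccuracy,
    filter_outliers,
    fit_gaussian,
    gaze_errors,
    high_accuracy_probability,
    kde_representative,
    pixels_to_degrees,
)
from gazekit.evaluation import fit_gaussian_mixture


class TestDegrees:
    def test_right_triangle_conversion(self):
        assert pixels_to_degrees(0, 0.27675, 450) == 0.0
        # 100 px at the user-study geometry: atan(27.675/450)
        expected = math.degrees(math.atan(100 * 0.27675 / 450.0))
        assert pixels_to_degrees(100, 0.27675, 450) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(3.5193, abs=2e-3)

    def test_monotone_in_offset(self):
        offs = np.linspace(0, 500, 40)
        vals = pixels_to_degrees(offs, 0.27675, 450)
        assert np.all(np.diff(vals) > 0)

    def test_distance_must_be_positive(self):
        with pytest.raises(ValueError):
            pixels_to_degrees(10, 0.3, 0.0)


class TestGazeErrors:
    def test_zero_when_estimate_equals_target(self):
        t = np.array([[10.0, 20.0], [-5.0, 3.0]])
        e = gaze_errors(t, t, 550.0)
        assert np.all(e.magnitude_deg == 0) and np.all(e.ex_deg == 0)

    def test_pure_x_offset(self):
        t = np.zeros((1, 2))
        est = np.array([[50.0, 0.0]])
        e = gaze_errors(est, t, 550.0)
        assert e.ey_deg[0] == 0.0
        assert e.magnitude_deg[0] == pytest.approx(abs(e.ex_deg[0]))

    def test_matches_per_point_recomputation(self, rng):
        est = rng.normal(scale=50, size=(100, 2))
        tgt = rng.normal(scale=50, size=(100, 2))
        e = gaze_errors(est, tgt, 450.0, pixel_size_mm=0.27675)
        for i in rng.integers(0, 100, 20):
            d = math.hypot(est[i, 0] - tgt[i, 0], est[i, 1] - tgt[i, 1])
            expect = math.degrees(math.atan(d * 0.27675 / 450.0))
            assert e.magnitude_deg[i] == pytest.approx(expect, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            gaze_errors(np.zeros((3, 2)), np.zeros((4, 2)), 100.0)


class TestGaussianFit:
    def test_recovers_distribution_parameters(self):
        r = np.random.default_rng(42)
        sample = r.normal(0.2, 0.1, 10_000)
        g = fit_gaussian(sample)
        assert g.mu == pytest.approx(0.2, abs=3 * 0.1 / 100.0)
        assert g.sigma == pytest.approx(0.1, rel=0.05)

    def test_constant_sample_is_point_mass(self):
        g = fit_gaussian(np.full(50, 0.3))
        assert g.mu == pytest.approx(0.3, abs=1e-12)
        assert g.sigma == pytest.approx(0.0, abs=1e-12)
        assert high_accuracy_probability(g) == 1.0
        g_out = fit_gaussian(np.full(50, 0.8))
        assert high_accuracy_probability(g_out) == 0.0

    def test_affine_equivariance(self, rng):
        x = rng.normal(size=500)
        g = fit_gaussian(x)
        g2 = fit_gaussian(3.0 * x + 1.0)
        assert g2.mu == pytest.approx(3 * g.mu + 1, abs=1e-12)
        assert g2.sigma == pytest.approx(3 * g.sigma, rel=1e-12)


class TestHighAccuracyBand:
    def test_one_sigma_band_mass(self):
        g = GaussianAccuracy(mu=0.0, sigma=0.5)
        assert high_accuracy_probability(g) == pytest.approx(0.6827, abs=1e-4)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(-2, 2), st.floats(0.01, 3))
    def test_agrees_with_quadrature_of_the_density(self, mu, sigma):
        """CDF-difference band mass equals numerical integration of the
        Gaussian density, and the total mass is 1 (conservation)."""
        g = GaussianAccuracy(mu=mu, sigma=sigma)

        def pdf(x):
            return math.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))

        ref, _ = quad(pdf, -0.5, 0.5, epsabs=1e-13)
        assert high_accuracy_probability(g) == pytest.approx(ref, abs=1e-10)
        total, _ = quad(pdf, mu - 12 * sigma, mu + 12 * sigma, epsabs=1e-13)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_monotone_in_sigma_and_mu(self):
        probs_sigma = [
            high_accuracy_probability(GaussianAccuracy(0.0, s))
            for s in np.linspace(0.1, 3.0, 15)
        ]
        assert np.all(np.diff(probs_sigma) < 0)
        probs_mu = [
            high_accuracy_probability(GaussianAccuracy(m, 0.4))
            for m in np.linspace(0.0, 2.5, 15)
        ]
        assert np.all(np.diff(probs_mu) < 0)

    def test_histogram_and_gaussian_band_agree_on_gaussian_data(self):
        r = np.random.default_rng(5)
        x = r.normal(0.1, 0.45, 200_000)
        g = fit_gaussian(x)
        hist = np.mean((x > -0.5) & (x < 0.5))
        assert abs(high_accuracy_probability(g) - hist) < 0.02


class TestMixture:
    def test_separates_two_clear_modes(self):
        r = np.random.default_rng(11)
        x = np.concatenate([r.normal(-1.0, 0.1, 3000), r.normal(1.0, 0.1, 1000)])
        comps = fit_gaussian_mixture(x)
        (w1, g1), (w2, g2) = comps
        assert w1 == pytest.approx(0.75, abs=0.03)
        assert sorted([g1.mu, g2.mu]) == pytest.approx([-1.0, 1.0], abs=0.03)


class TestKDE:
    def test_identical_points_return_that_point(self):
        pt = np.array([2.0, 3.0])
        assert np.allclose(kde_representative(np.tile(pt, (5, 1))), pt)

    def test_outliers_do_not_win(self, rng):
        cluster = rng.normal(0, 0.05, size=(60, 2))
        outliers = np.array([[8.0, 8.0], [-9.0, 7.0], [10.0, -10.0]])
        rep = kde_representative(np.vstack([cluster, outliers]))
        assert np.linalg.norm(rep) < 0.3

    def test_mode_near_mean_for_symmetric_cloud(self):
        r = np.random.default_rng(3)
        cloud = r.normal(0, 1.0, size=(400, 2))
        rep = kde_representative(cloud)
        bw = 400 ** (-1.0 / 6.0)  # Silverman exponent for d=2
        # the sample-restricted mode scatters on the bandwidth scale
        assert np.linalg.norm(rep - cloud.mean(axis=0)) < bw * cloud.std()

    def test_needs_five_samples(self):
        with pytest.raises(ValueError):
            kde_representative(np.zeros((4, 2)))


def _errorset(mags, meta=None):
    z = np.zeros_like(mags)
    return ErrorSet(ex_deg=mags, ey_deg=z, magnitude_deg=np.abs(mags),
                    ex_raw=mags, ey_raw=z, meta=meta or {})


class TestOutlierFilter:
    def test_clean_trials_untouched(self):
        trials = [_errorset(np.full(20, 0.4)), _errorset(np.full(15, 0.8))]
        kept, rep = filter_outliers(trials)
        assert rep["trials_removed"] == 0 and rep["samples_removed"] == 0
        assert rep["samples_out"] == 35

    def test_gross_trial_removed_whole(self):
        good = [_errorset(np.full(30, 0.5)) for _ in range(4)]
        bad = _errorset(np.full(30, 10.0))
        kept, rep = filter_outliers(good + [bad])
        assert rep["trials_removed"] == 1
        assert len(kept) == 4

    def test_three_sigma_rule_removes_expected_fraction(self):
        r = np.random.default_rng(9)
        trial = _errorset(r.normal(0.0, 1.0, 10_000))
        kept, rep = filter_outliers([trial])
        frac = rep["samples_removed"] / 10_000
        # the filter acts on error magnitudes: for |N(0,1)| the 3-sigma rule
        # keeps |x| < mean + 3*std ~ 2.606, so ~0.92% is removed
        expected = 2 * (1 - 0.5 * (1 + math.erf(2.606 / math.sqrt(2))))
        assert frac == pytest.approx(expected, abs=0.004)

    def test_empty_result_warns(self):
        with pytest.warns(UserWarning):
            filter_outliers([_errorset(np.full(10, 9.0))])
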