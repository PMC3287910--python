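"""Empirical-Bayes wavelet shrinkage against independent numeric oracles.

The posterior-median oracle integrates the spike-and-slab posterior by
quadrature and inverts its CDF by root finding; the weight oracle maximizes
the marginal likelihood on a dense grid.  Both are deliberately brute-force
and share no code with the analytic implementation they check.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize, stats

from wavescore.wavelet_denoise import (
    CoefficientPyramid,
    EBayesPosterior,
    WaveletConfig,
    denoise,
    denoise_matrix,
    dwt,
    estimate_noise_sd,
    idwt,
    marginal_mle_weight,
    posterior_median,
    threshold_value,
)
from wavescore.wavelet_denoise import _log_marginal_parts, _mixture_loglik

_RANGE = 40.0


def oracle_posterior_median(z, w, a, sigma=1.0):
    """Quadrature + CDF inversion for the spike-and-slab posterior median."""
    zs = z / sigma
    phi = stats.norm.pdf
    f = lambda u: 0.5 * a * np.exp(-a * np.abs(u)) * phi(zs - u)  # noqa: E731
    pts = sorted({0.0, float(np.clip(zs, -_RANGE, _RANGE))})
    g, _ = integrate.quad(f, -_RANGE, _RANGE, points=pts, limit=400)
    wpost = w * g / (w * g + (1 - w) * phi(zs))

    def cdf(m):
        if m <= -_RANGE:
            return 0.0
        inner = [p for p in pts if -_RANGE < p < m]
        cont, _ = integrate.quad(f, -_RANGE, m, points=inner or None, limit=400)
        return wpost * cont / g + (1 - wpost) * (m >= 0)

    if cdf(-1e-12) <= 0.5 <= cdf(1e-12):
        return 0.0
    return optimize.brentq(lambda m: cdf(m) - 0.5, -_RANGE, _RANGE, xtol=1e-10) * sigma


class TestPosteriorMedian:
    @pytest.mark.parametrize("z", [0.0, 0.5, 1.0, 2.0, 3.0, 5.0, -5.0, 8.0, -2.5])
    @pytest.mark.parametrize("w", [0.01, 0.1, 0.5, 0.9, 1.0])
    @pytest.mark.parametrize("a", [0.3, 0.5, 1.0])
    def test_matches_quadrature_oracle(self, z, w, a):
        post = EBayesPosterior(w=w, a=a, sigma=1.0)
        assert posterior_median(z, post) == pytest.approx(
            oracle_posterior_median(z, w, a), abs=1e-6
        )

    def test_noise_scale_folds_in(self):
        post = EBayesPosterior(w=0.5, a=0.5, sigma=2.0)
        assert posterior_median(6.0, post) == pytest.approx(
            oracle_posterior_median(6.0, 0.5, 0.5, sigma=2.0), abs=1e-6
        )

    def test_zero_maps_to_zero_and_antisymmetry(self):
        post = EBayesPosterior(w=0.4, a=0.5, sigma=1.0)
        assert posterior_median(0.0, post) == 0.0
        for z in (0.7, 2.3, 4.1):
            assert posterior_median(-z, post) == pytest.approx(-posterior_median(z, post))

    def test_pure_spike_always_zero(self):
        post = EBayesPosterior(w=0.0, a=0.5, sigma=1.0)
        assert posterior_median(5.0, post) == 0.0

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        z=st.floats(-30, 30),
        w=st.floats(0.01, 1.0),
        a=st.floats(0.1, 2.0),
    )
    def test_shrinks_toward_zero(self, z, w, a):
        post = EBayesPosterior(w=w, a=a, sigma=1.0)
        out = posterior_median(z, post)
        assert abs(out) <= abs(z) + 1e-12
        assert out * z >= 0 or out == 0.0


class TestThreshold:
    def test_defining_property(self):
        for w in (0.1, 0.5, 0.9):
            post = EBayesPosterior(w=w, a=0.5, sigma=1.0)
            t = threshold_value(w, 0.5, 1.0)
            assert posterior_median(t - 1e-6, post) == 0.0
            assert posterior_median(t + 1e-6, post) != 0.0

    def test_monotone_nonincreasing_in_w(self):
        ts = [threshold_value(w, 0.5, 1.0) for w in (0.05, 0.2, 0.5, 0.8, 1.0)]
        assert all(a >= b for a, b in zip(ts, ts[1:]))

    def test_boundary_weights(self):
        assert threshold_value(0.0, 0.5, 1.0) == math.inf
        assert threshold_value(1.0, 0.5, 1.0) < 1e-6  # slab dominates

    def test_scales_with_sigma(self):
        assert threshold_value(0.3, 0.5, 2.0) == pytest.approx(
            2 * threshold_value(0.3, 0.5, 1.0), rel=1e-6
        )


class TestMarginalMleWeight:
    def test_pure_noise_drives_w_down(self, rng):
        z = rng.normal(0, 1, 500)
        assert marginal_mle_weight(z, 0.5, 1.0) <= 0.1

    def test_half_spikes_drive_w_up(self, rng):
        z = np.concatenate([rng.normal(0, 1, 250), 10.0 * np.sign(rng.normal(size=250))])
        assert marginal_mle_weight(z, 0.5, 1.0) >= 0.4

    def test_always_in_unit_interval(self, rng):
        for _ in range(5):
            z = rng.normal(0, rng.uniform(0.5, 3), rng.integers(4, 100))
            assert 0.0 <= marginal_mle_weight(z, 0.5, 1.0) <= 1.0

    @pytest.mark.parametrize("mix", [0.0, 0.2, 0.6])
    def test_matches_grid_search_oracle(self, mix, rng):
        n = 400
        spikes = rng.random(n) < mix
        z = np.where(spikes, rng.laplace(0, 2.0, n), 0.0) + rng.normal(0, 1, n)
        lp, lm, lphi = _log_marginal_parts(z, 0.5)
        lg = np.logaddexp(lp, lm)
        grid = np.linspace(0, 1, 20001)
        vals = np.array([_mixture_loglik(np.array(g), lphi, lg) for g in grid])
        w_grid = grid[vals.argmax()]
        assert marginal_mle_weight(z, 0.5, 1.0) == pytest.approx(w_grid, abs=1e-4)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            marginal_mle_weight(np.array([1.0, np.nan]), 0.5, 1.0)


class TestTransform:
    def test_haar_hand_computation(self):
        pyr = dwt(np.array([1.0, 1.0, -1.0, -1.0]), WaveletConfig(max_level=1))
        np.testing.assert_allclose(pyr.approximation, [math.sqrt(2), -math.sqrt(2)])
        np.testing.assert_allclose(pyr.details[0], [0.0, 0.0])

    def test_constant_kills_details(self):
        pyr = dwt(np.full(16, 3.7))
        for d in pyr.details:
            np.testing.assert_allclose(d, 0.0, atol=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        n=st.integers(2, 130),
        family=st.sampled_from(["haar", "db2", "sym4"]),
        seed=st.integers(0, 2**16),
    )
    def test_perfect_reconstruction(self, n, family, seed):
        x = np.random.default_rng(seed).normal(size=n)
        cfg = WaveletConfig(family=family)
        assert np.abs(idwt(dwt(x, cfg)) - x).max() < 1e-10

    def test_length_one_rejected(self):
        with pytest.raises(ValueError):
            dwt(np.array([1.0]))

    def test_pyramid_accounting(self):
        pyr = dwt(np.arange(37, dtype=float))
        assert pyr.original_length == 37
        assert pyr.padded_length == 64
        assert pyr.total_coefficients() == 64


class TestNoiseSd:
    def test_all_zero_details(self):
        assert estimate_noise_sd(np.zeros(8)) == 0.0

    def test_mad_constant(self):
        d = np.array([-0.6745, 0.6745, 0.6745, -0.6745])
        assert estimate_noise_sd(d) == pytest.approx(1.0)

    def test_homogeneity(self, rng):
        d = rng.normal(size=64)
        assert estimate_noise_sd(10 * d) == pytest.approx(10 * estimate_noise_sd(d))

    def test_sparse_fallback_to_all_details(self):
        finest = np.zeros(16)
        alld = np.concatenate([finest, np.array([2.0, -2.0])])
        assert estimate_noise_sd(finest, alld) > 0


class TestDenoise:
    def test_zeros_and_constant_fixed_points(self):
        np.testing.assert_allclose(denoise(np.zeros(16)), 0.0, atol=1e-12)
        np.testing.assert_allclose(denoise(np.full(16, 2.5)), 2.5, atol=1e-10)

    def test_shrink_disabled_is_identity(self, rng):
        x = rng.normal(size=50)
        assert np.abs(denoise(x, shrink=False) - x).max() < 1e-10

    def test_noise_reduction_on_block_signal(self, rng):
        clean = np.concatenate([np.zeros(32), 2.0 * np.ones(32), np.zeros(64)])
        noisy = clean + rng.normal(0, 0.1, clean.size)
        den = denoise(noisy)
        assert np.mean((den - clean) ** 2) < np.mean((noisy - clean) ** 2)

    def test_detail_shrinkage_never_grows_coefficients(self, rng):
        from wavescore.wavelet_denoise import _shrink_pyramid

        x = rng.normal(0, 0.3, 60)
        pyr = dwt(x)
        shrunk = _shrink_pyramid(pyr, WaveletConfig())
        for before, after in zip(pyr.details, shrunk.details):
            assert np.all(np.abs(after) <= np.abs(before) + 1e-12)
        np.testing.assert_array_equal(shrunk.approximation, pyr.approximation)

    def test_isolated_rare_spike_survives(self, rng):
        x = np.zeros(64)
        x[30] = 5.0
        den = denoise(x + rng.normal(0, 0.05, 64))
        assert den[30] >= 2.5  # at least half the amplitude retained

    def test_matrix_rows_match_scalar_path(self, rng):
        X = rng.normal(0, 0.3, size=(6, 40))
        X[:, 17] += 4.0
        batch = denoise_matrix(X)
        rows = np.vstack([denoise(X[i]) for i in range(6)])
        np.testing.assert_allclose(batch, rows, atol=1e-12)

    def test_level_independent_mode_runs(self, rng):
        x = rng.normal(size=32)
        out = denoise(x, WaveletConfig(level_dependent=False))
        assert out.shape == x.shape and np.isfinite(out).all()
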