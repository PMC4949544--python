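"""Tests of the voxelwise maximum-likelihood reconstruction."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from relb1map import (
    DriveScheme,
    VoxelSeries,
    estimate_gamma_k,
    estimate_sigma,
    linear_signal,
    loglikelihood_k,
    make_drive_scheme,
    normalize,
    reconstruct_stack,
    reconstruct_voxel,
    select_kmax,
    SPGRParams,
)

LN2PI = np.log(2 * np.pi)


def series(signals, drives, sigma):
    return VoxelSeries(
        signals=tuple(signals), drives=DriveScheme(tuple(drives)), sigma=sigma
    )


def grid_maximize_loglik(norm, k, half_width=None, rounds=7, n=41):
    """Independent oracle: maximize the k-term log-likelihood over a complex
    grid around the data, repeatedly refining the grid around the best point.
    Evaluates the log-likelihood definition directly (sum of 2D Normal log
    densities of the first k normalized measurements)."""
    pts = np.asarray(norm.normalized[:k])
    sig = np.asarray(norm.sigmas[:k])
    center = pts.mean()
    if half_width is None:
        half_width = 2 * (np.abs(pts - center).max() + sig.max())
    best = center
    for _ in range(rounds):
        re = np.linspace(best.real - half_width, best.real + half_width, n)
        im = np.linspace(best.imag - half_width, best.imag + half_width, n)
        gg = re[None, :, None] + 1j * im[:, None, None]  # (n, n, 1)
        ll = np.sum(
            -np.log(2 * np.pi * sig**2) - np.abs(pts - gg) ** 2 / (2 * sig**2),
            axis=-1,
        )
        best = (re[None, :] + 1j * im[:, None]).ravel()[np.argmax(ll)]
        half_width *= 2.5 / (n - 1)
    return best


class TestNormalize:
    def test_zero_signals_stay_zero(self):
        norm = normalize(series([0, 0, 0], [0.1, 0.5, 1.0], 0.01))
        assert norm.normalized == (0, 0, 0)

    def test_unit_drives_are_identity(self):
        s = [1 + 2j, 0.5 - 1j]
        norm = normalize(series(s, [0.5, 1.0], 0.02))
        assert norm.normalized[1] == s[1]
        assert norm.sigmas[1] == 0.02

    def test_hand_example(self):
        norm = normalize(series([1.0, 0.5 + 0.5j], [0.1, 0.25], 0.01))
        assert norm.normalized[1] == pytest.approx(2 + 2j)
        assert norm.sigmas[1] == pytest.approx(0.04)

    def test_sigmas_strictly_decreasing(self):
        norm = normalize(series([1, 1, 1, 1], [0.1, 0.2, 0.5, 1.0], 0.03))
        assert np.all(np.diff(norm.sigmas) < 0)


class TestLogLikelihood:
    def test_zero_residual_single_term(self):
        norm = normalize(series([1.0], [0.1], 0.01))
        # L = -ln(2 pi) - 2 ln(sigma'_1), sigma'_1 = 0.1
        expected = -LN2PI - 2 * np.log(0.1)
        assert loglikelihood_k(norm, norm.normalized[0], 1) == pytest.approx(
            expected
        )
        assert expected == pytest.approx(2.7673, abs=1e-4)

    def test_additivity_of_zero_residual_terms(self):
        norm = normalize(series([0.5, 0.5], [0.5, 1.0], 0.02))
        l1 = loglikelihood_k(norm, 0.5, 1)
        l2 = loglikelihood_k(norm, 0.5, 2)
        assert l2 - l1 == pytest.approx(-LN2PI - 2 * np.log(0.02))

    def test_k_out_of_range(self):
        norm = normalize(series([1.0], [1.0], 0.1))
        with pytest.raises(ValueError):
            loglikelihood_k(norm, 1.0, 2)
        with pytest.raises(ValueError):
            estimate_gamma_k(norm, 0)


class TestGammaEstimate:
    def test_single_term_returns_first_sample(self):
        norm = normalize(series([2 - 1j, 5.0], [0.2, 1.0], 0.01))
        assert estimate_gamma_k(norm, 1) == norm.normalized[0]

    def test_constant_data_returns_the_constant(self):
        c = 1.5 + 0.5j
        norm = normalize(
            series([c * d for d in (0.1, 0.3, 1.0)], [0.1, 0.3, 1.0], 0.01)
        )
        for k in (1, 2, 3):
            assert estimate_gamma_k(norm, k) == pytest.approx(c)

    def test_drive_squared_weighting(self):
        # drives {0.1, 1}, S' = {2, 1}: (0.01*2 + 1*1)/1.01
        norm = normalize(series([0.2, 1.0], [0.1, 1.0], 0.01))
        assert estimate_gamma_k(norm, 2) == pytest.approx(1.0099009901)

    def test_matches_brute_force_grid_maximization(self, rng):
        """Closed-form estimate agrees with direct likelihood maximization."""
        for _ in range(60):
            N = int(rng.integers(2, 6))
            drives = np.sort(rng.uniform(0.05, 1.0, N))
            drives[-1] = 1.0
            sig = rng.uniform(0.005, 0.1)
            signals = (
                rng.normal(size=N) + 1j * rng.normal(size=N)
            ) * drives + rng.normal(scale=sig, size=N)
            norm = normalize(series(signals, drives, sig))
            k = int(rng.integers(1, N + 1))
            closed = estimate_gamma_k(norm, k)
            brute = grid_maximize_loglik(norm, k)
            scale = max(abs(closed), 1e-12)
            assert abs(closed - brute) / scale < 1e-6


class TestSelectKmax:
    def test_single_measurement(self):
        est = reconstruct_voxel(series([0.7 + 0.1j], [1.0], 0.05))
        assert est.k_max == 1
        assert est.gamma_hat == pytest.approx(0.7 + 0.1j)

    def test_rejects_grossly_saturated_second_drive(self):
        # normalized values {1.0, 0.5}: second drive saturated by 50 sigma'
        est = reconstruct_voxel(series([0.1, 0.5], [0.1, 1.0], 0.01))
        assert est.k_max == 1
        assert est.gamma_hat == pytest.approx(1.0)
        assert est.loglik[0] == pytest.approx(2.7673, abs=1e-4)
        assert est.loglik[1] == pytest.approx(-2.2365, abs=1e-4)

    def test_uses_all_drives_when_unsaturated(self):
        c = 0.8 + 0.3j
        drives = (0.1, 0.3, 1.0)
        est = reconstruct_voxel(series([c * d for d in drives], drives, 1e-4))
        assert est.k_max == 3
        assert est.gamma_hat == pytest.approx(c)

    def test_scale_equivariance(self):
        base = series([0.1, 0.5], [0.1, 1.0], 0.01)
        est = reconstruct_voxel(base)
        for c in (0.5, 3.0):
            scaled = series([c * s for s in base.signals], [0.1, 1.0], c * 0.01)
            est_c = reconstruct_voxel(scaled)
            assert est_c.k_max == est.k_max
            assert est_c.gamma_hat == pytest.approx(c * est.gamma_hat)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(alpha=st.floats(-np.pi, np.pi), data=st.data())
    def test_phase_equivariance(self, alpha, data):
        """Rotating all measurements rotates the estimate, nothing else."""
        N = data.draw(st.integers(2, 5))
        re = data.draw(
            st.lists(st.floats(-2, 2), min_size=N, max_size=N)
        )
        im = data.draw(
            st.lists(st.floats(-2, 2), min_size=N, max_size=N)
        )
        drives = np.linspace(0.2, 1.0, N)
        sig = 0.05
        signals = (np.array(re) + 1j * np.array(im)) * drives
        est = reconstruct_voxel(series(signals, drives, sig))
        rot = reconstruct_voxel(series(signals * np.exp(1j * alpha), drives, sig))
        assert rot.k_max == est.k_max
        assert rot.gamma_hat == pytest.approx(
            est.gamma_hat * np.exp(1j * alpha), abs=1e-9
        )
        assert np.allclose(rot.loglik, est.loglik, atol=1e-9)

    def test_saturation_rejection_in_noise_free_series(self):
        # depress drives beyond the second by many sigma': k_max stays <= 2
        drives = np.array([0.05, 0.2, 0.6, 1.0])
        sig = 1e-3
        truth = 1.0
        normalized = np.array([truth, truth, 0.6 * truth, 0.3 * truth])
        est = reconstruct_voxel(series(normalized * drives, drives, sig))
        assert est.k_max == 2
        assert est.gamma_hat == pytest.approx(truth, rel=1e-6)


class TestReconstructStack:
    def test_single_voxel_matches_scalar_path(self, rng):
        drives = DriveScheme((0.1, 0.4, 1.0))
        sig = 0.02
        signals = rng.normal(size=3) + 1j * rng.normal(size=3)
        stack = signals.reshape(1, 3, 1, 1)
        gamma, kmax = reconstruct_stack(stack, drives, sig)
        est = reconstruct_voxel(series(signals, drives.drives, sig))
        assert gamma[0, 0, 0] == pytest.approx(est.gamma_hat)
        assert kmax[0, 0, 0] == est.k_max

    def test_vectorized_equals_voxelwise(self, rng):
        drives = DriveScheme((0.05, 0.2, 0.5, 1.0))
        sig = 0.05
        stack = rng.normal(size=(2, 4, 3, 5)) + 1j * rng.normal(size=(2, 4, 3, 5))
        gamma, kmax = reconstruct_stack(stack, drives, sig)
        for c in range(2):
            for y in range(3):
                for x in range(5):
                    est = reconstruct_voxel(
                        series(stack[c, :, y, x], drives.drives, sig)
                    )
                    assert gamma[c, y, x] == pytest.approx(est.gamma_hat)
                    assert kmax[c, y, x] == est.k_max

    def test_noise_free_linear_stack_recovers_rho_f(self, rng):
        # forward model exactly linear: gamma equals rho*f at every voxel
        p = SPGRParams(TR=10.0, T1=1000.0, theta_ref=np.deg2rad(60.0))
        drives = DriveScheme((0.1, 0.3, 1.0))
        f = rng.uniform(0.05, 1.0, size=(2, 8, 8))
        stack = np.stack(
            [
                np.stack([linear_signal(p, f[c], np.full_like(f[c], d)) for d in drives.drives])
                for c in range(2)
            ]
        )
        gamma, kmax = reconstruct_stack(stack, drives, sigma=1e-9)
        assert np.allclose(gamma, p.rho * f, rtol=1e-10)
        assert np.all(kmax == 3)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            reconstruct_stack(np.zeros((2, 3, 4, 4)), DriveScheme((0.5, 1.0)), 0.1)
        with pytest.raises(ValueError):
            reconstruct_stack(np.zeros((2, 2, 4, 4)), DriveScheme((0.5, 1.0)), -1.0)


class TestEstimateSigma:
    def test_recovers_known_noise_level(self, rng):
        sig = 0.37
        draws = rng.normal(scale=sig, size=(200, 2))
        est = estimate_sigma(draws[:, 0] + 1j * draws[:, 1])
        assert est == pytest.approx(sig, rel=0.10)

    def test_constant_background_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert estimate_sigma(np.full(50, 2 + 3j)) == 0.0

    def test_pure_real_alternating_perturbation(self):
        a = 0.25
        vals = 1.0 + a * np.resize([1.0, -1.0], 40) + 0j
        assert estimate_sigma(vals) == pytest.approx(a / np.sqrt(2))

    def test_requires_enough_samples(self):
        with pytest.raises(ValueError):
            estimate_sigma(np.zeros(10, dtype=complex))
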