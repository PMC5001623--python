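"""Gas-of-near-circles prior: kernel, energies, gradients, calibration."""

import numpy as np
import pytest

from mlgoc._operators import convolve_zero_direct, forward_gradient
from mlgoc.goc import (
    CalibrationError,
    GOCParams,
    build_interaction_kernel,
    calibrate_for_radius,
    circle_energy_profile,
    geometric_energy,
    geometric_gradient,
    interaction_profile,
    render_circle_field,
)

from conftest import calibrated


class TestInteractionKernel:
    def test_plateau_midpoint_and_support(self):
        d, eps = 10.0, 5.0
        assert interaction_profile(np.array(0.0), d, eps) == 1.0
        assert interaction_profile(np.array(d), d, eps) == pytest.approx(0.5)
        assert interaction_profile(np.array(d + eps + 1.0), d, eps) == 0.0

    @pytest.mark.parametrize("d,eps", [(10.0, 5.0), (15.0, 7.5), (4.0, 4.0)])
    def test_kernel_invariants(self, d, eps):
        k = build_interaction_kernel(d, eps)
        v = k.values
        m = v.shape[0] // 2
        assert v[m, m] == 1.0
        assert v.min() >= 0.0 and v.max() <= 1.0
        yy, xx = np.mgrid[-m : m + 1, -m : m + 1]
        rr = np.hypot(yy, xx)
        assert np.all(v[rr >= d + eps] == 0.0)
        # radially non-increasing: sort samples by radius
        order = np.argsort(rr.ravel())
        vs = v.ravel()[order]
        rs = rr.ravel()[order]
        # allow ties at equal radius; check against running minimum of
        # all strictly smaller radii
        run_min = np.minimum.accumulate(vs)
        for i in range(1, len(vs)):
            if rs[i] > rs[i - 1]:
                assert vs[i] <= run_min[i - 1] + 1e-12

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            build_interaction_kernel(-1.0, 1.0)
        with pytest.raises(ValueError):
            build_interaction_kernel(5.0, 6.0)
        with pytest.raises(ValueError):
            build_interaction_kernel(5.0, 0.0)


class TestGeometricEnergy:
    @pytest.mark.parametrize("value,sign", [(-1.0, -1.0), (1.0, 1.0)])
    def test_constant_field_closed_form(self, small_goc, small_kernel, value, sign):
        n = 20
        field = np.full((n, n), value)
        expected = n * n * (-small_goc.lambda_f / 4.0 + sign * 2.0 * small_goc.alpha_f / 3.0)
        assert geometric_energy(field, small_goc, small_kernel) == pytest.approx(expected)

    def test_nonlocal_term_matches_direct_double_sum(self, small_goc, small_kernel, rng):
        """FFT-convolution nonlocal energy equals the O(N^2) pairwise sum."""
        for _ in range(5):
            phi = rng.uniform(-1.0, 1.0, (32, 32))
            e_fast = geometric_energy(phi, small_goc, small_kernel)
            gy, gx = forward_gradient(phi)
            cy = convolve_zero_direct(gy, small_kernel.values)
            cx = convolve_zero_direct(gx, small_kernel.values)
            e_nl_direct = 0.5 * float(np.sum(gy * cy + gx * cx))
            e_local = geometric_energy(
                phi,
                GOCParams(
                    D=small_goc.D,
                    lambda_f=small_goc.lambda_f,
                    alpha_f=small_goc.alpha_f,
                    beta_f=0.0,
                    d=small_goc.d,
                    epsilon=small_goc.epsilon,
                    r_hat=small_goc.r_hat,
                ),
                small_kernel,
            )
            e_direct = e_local - small_goc.beta_f * e_nl_direct
            assert e_fast == pytest.approx(e_direct, rel=1e-6)


class TestGeometricGradient:
    def test_constant_background_is_stationary(self, small_goc, small_kernel):
        field = np.full((16, 16), -1.0)
        g = geometric_gradient(field, small_goc, small_kernel)
        assert np.abs(g).max() == pytest.approx(0.0, abs=1e-12)

    def test_finite_difference_directional(self, small_goc, small_kernel, rng):
        phi = rng.uniform(-1.0, 1.0, (24, 24))
        g = geometric_gradient(phi, small_goc, small_kernel)
        h = 1e-6
        for _ in range(20):
            direction = rng.normal(size=phi.shape)
            ep = geometric_energy(phi + h * direction, small_goc, small_kernel)
            em = geometric_energy(phi - h * direction, small_goc, small_kernel)
            fd = (ep - em) / (2 * h)
            an = float(np.sum(g * direction))
            assert an == pytest.approx(fd, rel=1e-4)

    def test_linearity_in_beta(self, small_goc, small_kernel, rng):
        phi = rng.uniform(-1.0, 1.0, (20, 20))
        from dataclasses import replace

        b = small_goc.beta_f
        g1 = geometric_gradient(phi, replace(small_goc, beta_f=b), small_kernel)
        g2 = geometric_gradient(phi, replace(small_goc, beta_f=2 * b), small_kernel)
        g0 = geometric_gradient(phi, replace(small_goc, beta_f=0.0), small_kernel)
        np.testing.assert_allclose(g2 - g1, g1 - g0, rtol=1e-10, atol=1e-12)


class TestCircleProfileAndCalibration:
    def test_translation_invariance(self, small_goc, small_kernel):
        n = 48
        c = (n - 1) / 2
        f1 = render_circle_field((n, n), (c, c), 5.0)
        f2 = render_circle_field((n, n), (c + 3, c + 3), 5.0)
        e1 = geometric_energy(f1, small_goc, small_kernel)
        e2 = geometric_energy(f2, small_goc, small_kernel)
        assert e1 == pytest.approx(e2, rel=1e-9)

    def test_profile_is_energy_of_rendered_field(self, small_goc, small_kernel):
        prof = circle_energy_profile(small_goc, small_kernel, [4.0], relative_to_background=False)
        (r, e), = prof
        # re-render on the same grid size used internally
        from mlgoc.goc import _profile_grid_shape

        n = _profile_grid_shape(4.0, small_kernel)
        c = (n - 1) / 2
        field = render_circle_field((n, n), (c, c), 4.0)
        assert e == pytest.approx(geometric_energy(field, small_goc, small_kernel))

    def test_invalid_radius(self, small_goc, small_kernel):
        with pytest.raises(ValueError):
            circle_energy_profile(small_goc, small_kernel, [0.0])

    def test_calibrated_profile_minimum_r15(self):
        goc = calibrated(15.0)
        from mlgoc.goc import build_interaction_kernel as bik

        kernel = bik(goc.d, goc.epsilon)
        radii = np.arange(5.0, 30.5, 0.5)
        prof = circle_energy_profile(goc, kernel, radii)
        rs, es = zip(*prof)
        r_star = rs[int(np.argmin(es))]
        assert 14.0 <= r_star <= 16.0
        assert min(es) < 0.0  # circle creation favourable
        assert max(es[: int(np.argmin(es)) + 1]) > 0.0  # nucleation barrier

    def test_calibration_monotone_in_radius(self):
        g10, g20 = calibrated(10.0), calibrated(20.0)
        from mlgoc.goc import build_interaction_kernel as bik

        def argmin_radius(goc):
            kernel = bik(goc.d, goc.epsilon)
            radii = np.arange(goc.r_hat / 2, 2 * goc.r_hat, 0.5)
            prof = circle_energy_profile(goc, kernel, radii)
            rs, es = zip(*prof)
            return rs[int(np.argmin(es))]

        assert argmin_radius(g20) > argmin_radius(g10)

    def test_calibration_failure_reports_profile(self):
        # an interaction range far too small for the requested radius
        # admits no stable minimum within the search bounds
        with pytest.raises(CalibrationError):
            calibrate_for_radius(40.0, d=2.0, epsilon=1.0, beta_grid=np.array([1e-3, 1e-2]))
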