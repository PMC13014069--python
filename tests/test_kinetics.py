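"""Unit and property tests for the 1TC basis-function kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pet4d import (FrameSchedule, InputFunction, KineticParams,
                   OneTissueBasisModel, convolve_exponential,
                   fit_parametric_image, fit_tac, frame_average, frame_weights,
                   make_basis_set, simulate_tac)


def ramp_then_constant(c=100.0, t1=0.5, duration=60.0):
    """Cp rising linearly to c over [0, t1], constant afterwards."""
    return InputFunction(np.array([0.0, t1, duration]), np.array([0.0, c, c]))


def ramp_response(t, k2, slope):
    """Closed form of exp(-k2 t) (x) (slope * t)."""
    return slope * (t / k2 - (1.0 - np.exp(-k2 * t)) / k2**2)


class TestConvolveExponential:
    def test_matches_closed_form_for_piecewise_linear_cp(self):
        # Cp = b*t - b*(t-t1)_+  =>  response is the superposition of two
        # ramp responses; exact for the analytic convolution
        c, t1, k2 = 100.0, 0.5, 0.1
        b = c / t1
        cpf = ramp_then_constant(c, t1)
        t, out = convolve_exponential(cpf, k2, fine_dt=0.01, t_end=10.0)
        expected = ramp_response(t, k2, b)
        late = t >= t1
        expected[late] -= ramp_response(t[late] - t1, k2, b)
        assert np.allclose(out, expected, rtol=1e-10, atol=1e-10)

    def test_constant_cp_long_time_limit(self):
        # past the ramp the response approaches c*(1 - e^{-k2 t})/k2
        c, k2 = 50.0, 0.2
        cpf = ramp_then_constant(c, t1=0.01)
        t, out = convolve_exponential(cpf, k2, fine_dt=0.01, t_end=30.0)
        ref = c * (1.0 - np.exp(-k2 * t[-1])) / k2
        assert out[-1] == pytest.approx(ref, rel=1e-3)

    def test_zero_input_gives_zero_output(self):
        cpf = InputFunction(np.array([0.0, 60.0]), np.array([0.0, 0.0]))
        _, out = convolve_exponential(cpf, 0.05)
        assert np.all(out == 0.0)

    def test_matches_fine_quadrature_oracle(self):
        # arbitrary piecewise-linear Cp with knots on the fine grid
        knots = np.array([0.0, 0.3, 0.7, 1.5, 5.0, 20.0, 60.0])
        vals = np.array([0.0, 80.0, 30.0, 22.0, 10.0, 4.0, 1.0])
        cpf = InputFunction(knots, vals)
        k2 = 0.05
        t, out = convolve_exponential(cpf, k2, fine_dt=0.01)
        # brute-force quadrature at dt = 1e-4 min (trapezoidal Riemann sum)
        dt = 1e-4
        tq = np.arange(0, 60.0 + dt / 2, dt)
        cq = cpf(tq)
        for tc in (0.5, 2.0, 10.0, 59.0):
            m = tq <= tc + dt / 2
            integrand = np.exp(-k2 * (tc - tq[m])) * cq[m]
            ref = np.trapezoid(integrand, dx=dt)
            got = out[np.argmin(np.abs(t - tc))]
            assert got == pytest.approx(ref, rel=1e-6)

    def test_invalid_arguments_raise(self):
        cpf = ramp_then_constant()
        with pytest.raises(ValueError):
            convolve_exponential(cpf, -0.1)
        with pytest.raises(ValueError):
            convolve_exponential(cpf, 0.1, fine_dt=-1.0)
        with pytest.raises(ValueError):
            InputFunction(np.array([0.0, 1.0, 1.0]), np.array([0.0, 1.0, 2.0]))


class TestFrameAverage:
    def test_constant_tac(self, schedule):
        t = np.arange(0, 6001) * 0.01
        out = frame_average(t, np.full_like(t, 7.0), schedule)
        assert np.allclose(out, 7.0)

    def test_linear_tac_gives_frame_midpoints(self, schedule):
        t = np.arange(0, 6001) * 0.01
        out = frame_average(t, t, schedule)
        assert np.allclose(out, schedule.midpoints, atol=1e-9)

    def test_exponential_tac_matches_analytic_integral(self, schedule):
        lam = 0.07
        t = np.arange(0, 600001) * 1e-4
        out = frame_average(t, np.exp(-lam * t), schedule)
        s, e = schedule.frame_starts, schedule.frame_ends
        ref = (np.exp(-lam * s) - np.exp(-lam * e)) / (lam * (e - s))
        assert np.allclose(out, ref, rtol=1e-6)

    def test_short_grid_raises(self, schedule):
        t = np.arange(0, 100) * 0.01
        with pytest.raises(ValueError):
            frame_average(t, t, schedule)


class TestBasisSet:
    def test_geometric_grid_endpoints_and_ratio(self, basis_small):
        g = basis_small.k2_grid
        assert g[0] == pytest.approx(0.005)
        assert g[-1] == pytest.approx(1.0)
        ratios = g[1:] / g[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_two_bases(self, cp, schedule):
        bs = make_basis_set(cp, schedule, n_bases=2, k2_min=0.01, k2_max=0.5)
        assert np.allclose(bs.k2_grid, [0.01, 0.5])

    def test_basis_frames_nonnegative(self, basis_small):
        assert np.all(basis_small.basis_frames >= 0)

    def test_basis_row_matches_independent_computation(self, cp, schedule,
                                                       basis_small):
        for b in (0, 17, 49):
            k2 = basis_small.k2_grid[b]
            t, v = convolve_exponential(cp, k2, 0.01,
                                        t_end=schedule.total_duration)
            ref = frame_average(t, v, schedule)
            assert np.allclose(basis_small.basis_frames[b], ref, rtol=1e-12)

    def test_invalid_range_raises(self, cp, schedule):
        with pytest.raises(ValueError):
            make_basis_set(cp, schedule, n_bases=10, k2_min=0.5, k2_max=0.1)

    def test_basis_value_decreasing_in_k2_past_peak(self, cp, schedule,
                                                    basis_small):
        # at the last frame (well past the Cp peak) the unit-K1 basis TAC is
        # strictly decreasing in k2
        last = basis_small.basis_frames[:, -1]
        assert np.all(np.diff(last) < 0)


class TestSimulateTac:
    def test_zero_k1(self, cp, schedule):
        assert np.all(simulate_tac(0.0, 0.05, cp, schedule) == 0)

    def test_composition_matches_convolution(self, cp, schedule):
        K1, k2 = 0.3, 0.05
        t, v = convolve_exponential(cp, k2, 0.01, t_end=schedule.total_duration)
        ref = K1 * frame_average(t, v, schedule)
        assert np.allclose(simulate_tac(K1, k2, cp, schedule), ref, rtol=1e-12)


def brute_force_fit(tac, basis_set, weights, fit_mask):
    """Independent exhaustive scan over the basis grid (loop implementation)."""
    w = np.asarray(weights) * np.asarray(fit_mask, dtype=float)
    best = (np.inf, None, None)
    for b in range(basis_set.n_bases):
        Bb = basis_set.basis_frames[b]
        den = np.sum(w * Bb * Bb)
        k1 = max(np.sum(w * Bb * tac) / den, 0.0)
        sse = np.sum(w * (tac - k1 * Bb) ** 2)
        if sse < best[0] - 1e-15:
            best = (sse, k1, b)
    return best[1], basis_set.k2_grid[best[2]]


class TestFitTac:
    def test_noiseless_on_grid_recovery(self, cp, schedule, basis_small):
        k2 = basis_small.k2_grid[23]
        tac = simulate_tac(0.4, k2, cp, schedule)
        p = fit_tac(tac, basis_small)
        assert p.k2 == pytest.approx(k2, rel=1e-12)
        assert p.K1 == pytest.approx(0.4, rel=1e-6)
        assert p.VT * p.k2 == pytest.approx(p.K1, rel=1e-12)

    def test_all_zero_tac_ties_to_smallest_k2(self, schedule, basis_small):
        p = fit_tac(np.zeros(schedule.n_frames), basis_small)
        assert p.K1 == 0.0 and p.VT == 0.0
        assert p.k2 == basis_small.k2_min
        assert p.hit_lower_bound

    def test_matches_exhaustive_scan_on_noisy_tacs(self, cp, schedule,
                                                   basis_small):
        rng = np.random.default_rng(5)
        w = frame_weights(schedule)
        for _ in range(100):
            k1 = rng.uniform(0.1, 0.5)
            k2 = rng.uniform(0.01, 0.1)
            tac = simulate_tac(k1, k2, cp, schedule)
            tac += rng.normal(0, 0.05 * tac.max(), size=tac.shape)
            p = fit_tac(tac, basis_small, weights=w)
            k1_ref, k2_ref = brute_force_fit(tac, basis_small, w,
                                             schedule.fit_mask)
            assert p.k2 == pytest.approx(k2_ref, rel=1e-12)
            assert p.K1 == pytest.approx(k1_ref, rel=1e-10, abs=1e-12)

    def test_off_grid_k2_recovers_neighboring_grid_point(self, cp, schedule,
                                                         basis_small):
        g = basis_small.k2_grid
        k2 = np.sqrt(g[10] * g[11])  # between two grid points
        tac = simulate_tac(0.3, k2, cp, schedule)
        p = fit_tac(tac, basis_small)
        assert p.k2 in (g[10], g[11])

    def test_error_on_all_zero_weights(self, schedule, basis_small):
        with pytest.raises(ValueError):
            fit_tac(np.ones(schedule.n_frames), basis_small,
                    weights=np.zeros(schedule.n_frames))

    def test_error_on_nan(self, schedule, basis_small):
        tac = np.ones(schedule.n_frames)
        tac[3] = np.nan
        with pytest.raises(ValueError):
            fit_tac(tac, basis_small)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(alpha=st.floats(0.1, 10.0), k2_idx=st.integers(2, 47))
    def test_scale_equivariance(self, cp, schedule, basis_small, alpha, k2_idx):
        """Scaling TAC and Cp jointly leaves (K1, k2) unchanged; scaling the
        TAC alone scales K1 by alpha and leaves k2 unchanged."""
        k2 = basis_small.k2_grid[k2_idx]
        tac = simulate_tac(0.3, k2, cp, schedule)
        p0 = fit_tac(tac, basis_small)
        p1 = fit_tac(alpha * tac, basis_small)
        assert p1.k2 == pytest.approx(p0.k2, rel=1e-12)
        assert p1.K1 == pytest.approx(alpha * p0.K1, rel=1e-9)


class TestFitParametricImage:
    def test_uniform_image_equals_single_fit(self, cp, schedule, basis_small):
        tac = simulate_tac(0.25, 0.03, cp, schedule)
        img = np.tile(tac, (4, 4, 1))
        pimg = fit_parametric_image(img, basis_small)
        ref = fit_tac(tac, basis_small)
        assert np.allclose(pimg.K1, ref.K1)
        assert np.allclose(pimg.k2, ref.k2)

    def test_zero_image(self, schedule, basis_small):
        pimg = fit_parametric_image(np.zeros((3, 3, schedule.n_frames)),
                                    basis_small)
        assert np.all(pimg.K1 == 0)
        assert np.all(pimg.VT == 0)

    def test_voxelwise_equality_with_looped_fit(self, cp, schedule,
                                                basis_small):
        rng = np.random.default_rng(9)
        img = np.empty((8, 8, schedule.n_frames))
        for i in range(8):
            for j in range(8):
                tac = simulate_tac(rng.uniform(0.1, 0.5),
                                   rng.uniform(0.01, 0.2), cp, schedule)
                img[i, j] = tac + rng.normal(0, 0.03 * tac.max(), tac.shape)
        pimg = fit_parametric_image(img, basis_small)
        for i in range(8):
            for j in range(8):
                ref = fit_tac(img[i, j], basis_small)
                assert pimg.K1[i, j] == pytest.approx(ref.K1, rel=1e-10)
                assert pimg.k2[i, j] == pytest.approx(ref.k2, rel=1e-12)

    def test_vt_identity_everywhere(self, cp, schedule, basis_small):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 100, size=(5, 5, schedule.n_frames))
        pimg = fit_parametric_image(img, basis_small)
        pos = pimg.K1 > 0
        assert np.allclose(pimg.VT[pos] * pimg.k2[pos], pimg.K1[pos],
                           rtol=1e-12)

    def test_shape_mismatch_raises(self, basis_small):
        with pytest.raises(ValueError):
            fit_parametric_image(np.zeros((4, 4, 7)), basis_small)


class TestModelInterface:
    def test_results_summary_and_residuals(self, cp, schedule, basis_small):
        tac = simulate_tac(0.3, basis_small.k2_grid[20], cp, schedule)
        res = OneTissueBasisModel(tac, basis_small).fit()
        assert "K1" in res.summary()
        assert res.weighted_sse() == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.fittedvalues, tac, rtol=1e-6)

    def test_frame_weight_modes(self, schedule):
        wu = frame_weights(schedule, "uniform")
        wd = frame_weights(schedule, "duration-decay")
        wi = frame_weights(schedule, "inv-var",
                           frame_sd=np.ones(schedule.n_frames))
        for w in (wu, wd, wi):
            assert w.sum() == pytest.approx(1.0)
        # later long frames decay away relative to pure duration weighting
        assert wd[-1] < wd[11]
        with pytest.raises(ValueError):
            frame_weights(schedule, "inv-var",
                          frame_sd=np.zeros(schedule.n_frames))
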