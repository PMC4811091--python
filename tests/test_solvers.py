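import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ewistars as ew
from ewistars.solvers import _apply_A
from ewistars.transforms import dwt_forward, dwt_inverse


class TestShrink:
    @pytest.mark.parametrize("z,b,expected", [
        (3.0, 2.0, 2.0),        # sgn(3)(3 - min(1, 3))
        (-0.3, 2.0, 0.0),       # min(1, 0.3) annihilates
        (-3.0, 2.0, -2.0),
        (0.0, 5.0, 0.0),
    ])
    def test_closed_form_values(self, z, b, expected):
        assert ew.shrink(z, b) == pytest.approx(expected)

    def test_zero_threshold_is_identity(self, rng):
        z = rng.standard_normal(100)
        assert np.array_equal(ew.shrink(z, 0.0), z)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            ew.shrink(1.0, -0.1)

    @given(st.floats(-100, 100), st.floats(-100, 100), st.floats(0, 50))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_nonexpansive(self, z1, z2, b):
        assert abs(ew.shrink(z1, b) - ew.shrink(z2, b)) <= abs(z1 - z2) + 1e-12

    @given(st.floats(-100, 100), st.floats(0, 50))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_never_grows_or_flips_sign(self, z, b):
        out = ew.shrink(z, b)
        assert abs(out) <= abs(z) + 1e-12
        assert out * z >= 0


class TestCost:
    def test_zero_coefficients_give_data_energy(self, kspace64):
        spec = ew.WaveletSpec("db2", 4)
        omega = dwt_forward(np.zeros((64, 64)), spec)
        expected = float(np.sum(np.abs(kspace64.values[kspace64.mask.keep]) ** 2))
        assert ew.cost(omega, kspace64, lam=3.0) == pytest.approx(expected)

    def test_exact_coefficients_noiseless_full_mask(self, phantom64):
        spec = ew.WaveletSpec("db1", 4)
        full = ew.make_mask((64, 64), 1.0)
        y = ew.forward_model(phantom64, full, 0.0)
        omega = dwt_forward(phantom64, spec)
        data_term = ew.cost(omega, y, lam=0.0 + 1e-300)
        assert data_term <= 1e-10 * np.sum(np.abs(y.values) ** 2)

    def test_convexity_midpoint(self, kspace64, rng):
        spec = ew.WaveletSpec("db2", 3)
        for _ in range(5):
            w1 = dwt_forward(rng.uniform(-50, 50, (64, 64)), spec)
            w2 = dwt_forward(rng.uniform(-50, 50, (64, 64)), spec)
            mid = w1.copy_with(0.5 * (w1.array + w2.array))
            lhs = ew.cost(mid, kspace64, lam=5.0)
            rhs = 0.5 * (ew.cost(w1, kspace64, lam=5.0)
                         + ew.cost(w2, kspace64, lam=5.0))
            assert lhs <= rhs + 1e-9 * rhs


class TestISTA:
    def test_cost_trace_non_increasing(self, kspace64, phantom64):
        cfg = ew.SolverConfig(wavelet=ew.WaveletSpec("db2", 4), J=2.0,
                              max_iter=40, seed=5)
        r = ew.ista_solve(kspace64, cfg, phantom64)
        assert np.all(np.diff(r.cost_trace) <= 1e-8 * r.cost_trace[0])
        assert r.iterations_run == 40
        assert len(r.psnr_trace) == 40

    def test_full_sampling_noiseless_recovery(self, phantom64):
        full = ew.make_mask((64, 64), 1.0)
        y = ew.forward_model(phantom64, full, 0.0)
        cfg = ew.SolverConfig(lam=1e-6, J=2.0, wavelet=ew.WaveletSpec("db1", 4),
                              max_iter=100)
        r = ew.ista_solve(y, cfg)
        rel = np.linalg.norm(r.estimate - phantom64) / np.linalg.norm(phantom64)
        assert rel <= 1e-3

    def test_lasso_closed_form_oracle(self, phantom64):
        """With an orthonormal system (full mask, Haar) the l1 minimizer is the
        soft-thresholded analysis coefficients — ISTA must land on it."""
        spec = ew.WaveletSpec("db1", 4)
        full = ew.make_mask((64, 64), 1.0)
        y = ew.forward_model(phantom64, full, 0.0)
        lam = 50.0
        r = ew.ista_solve(y, ew.SolverConfig(lam=lam, J=2.0, wavelet=spec,
                                             max_iter=5))
        a = dwt_forward(phantom64, spec)
        closed = dwt_inverse(a.copy_with(ew.shrink(a.array, lam)))
        assert np.abs(r.estimate - closed).max() <= 1e-8

    def test_first_step_from_zero_matches_unrolled_form(self, kspace64):
        spec = ew.WaveletSpec("db2", 4)
        J, lam = 2.0, 10.0
        a = dwt_forward(np.real(ew.apply_U_adjoint(kspace64.values, kspace64.mask)),
                        spec)
        zero = a.copy_with(np.zeros_like(a.array))
        stepped = ew.shrink(
            zero.array + (2 / J) * (a.array - _apply_A(zero, kspace64.mask)),
            2 * lam / J)
        assert np.abs(stepped - ew.shrink((2 / J) * a.array, 2 * lam / J)).max() == 0

    def test_small_J_warns(self, kspace64):
        cfg = ew.SolverConfig(wavelet=ew.WaveletSpec("db1", 4), J=0.5, max_iter=2)
        with pytest.warns(UserWarning, match="majorization"):
            ew.ista_solve(kspace64, cfg)

    def test_inputs_unmodified(self, kspace64, phantom64):
        before_y = kspace64.values.copy()
        before_m = kspace64.mask.keep.copy()
        ew.ista_solve(kspace64, ew.SolverConfig(wavelet=ew.WaveletSpec("db2", 3),
                                                max_iter=3), phantom64)
        assert np.array_equal(kspace64.values, before_y)
        assert np.array_equal(kspace64.mask.keep, before_m)


class TestFISTA:
    def test_final_cost_not_worse_than_ista(self, kspace64, phantom64):
        cfg = ew.SolverConfig(wavelet=ew.WaveletSpec("db2", 4), J=2.0,
                              max_iter=100, seed=5)
        ri = ew.ista_solve(kspace64, cfg, phantom64)
        rf = ew.fista_solve(kspace64, cfg, phantom64)
        assert rf.cost_trace[-1] <= ri.cost_trace[-1]

    def test_full_sampling_recovery(self, phantom64):
        full = ew.make_mask((64, 64), 1.0)
        y = ew.forward_model(phantom64, full, 0.0)
        cfg = ew.SolverConfig(lam=1e-6, J=2.0, wavelet=ew.WaveletSpec("db1", 4),
                              max_iter=50)
        r = ew.fista_solve(y, cfg)
        rel = np.linalg.norm(r.estimate - phantom64) / np.linalg.norm(phantom64)
        assert rel <= 1e-3


class TestEWISTARS:
    def test_requires_positive_k(self, kspace64):
        with pytest.raises(ValueError):
            ew.ewistars_solve(kspace64, ew.SolverConfig(
                ewt_k=0, wavelet=ew.WaveletSpec("db1", 4), max_iter=2))

    def test_bit_identical_reruns(self, kspace64, phantom64):
        cfg = ew.SolverConfig(wavelet=ew.WaveletSpec("bior4.4", 4), ewt_k=6,
                              max_iter=10, seed=21)
        r1 = ew.ewistars_solve(kspace64, cfg, phantom64)
        r2 = ew.ewistars_solve(kspace64, cfg, phantom64)
        assert np.array_equal(r1.estimate, r2.estimate)
        assert np.array_equal(r1.cost_trace, r2.cost_trace)
        assert r1.shift_log == r2.shift_log

    def test_shift_log_recorded(self, kspace64):
        cfg = ew.SolverConfig(wavelet=ew.WaveletSpec("db2", 3), ewt_k=2,
                              max_iter=7, seed=3)
        r = ew.ewistars_solve(kspace64, cfg)
        assert len(r.shift_log) == 7
        off = ew.ewistars_solve(kspace64, ew.SolverConfig(
            wavelet=ew.WaveletSpec("db2", 3), ewt_k=2, max_iter=4,
            shift_enabled=False))
        assert all(s == ew.ShiftVector(0, 0) for s in off.shift_log)

    def test_consistency_limit_recovers_image(self, phantom64):
        full = ew.make_mask((64, 64), 1.0)
        y = ew.forward_model(phantom64, full, 0.0)
        cfg = ew.SolverConfig(lam=1e-6, wavelet=ew.WaveletSpec("db1", 4),
                              ewt_k=1, shift_enabled=False, max_iter=50)
        r = ew.ewistars_solve(y, cfg)
        rel = np.linalg.norm(r.estimate - phantom64) / np.linalg.norm(phantom64)
        assert rel <= 1e-2

    def test_loop_body_matches_linear_ista_update(self, kspace64, rng):
        """Data-consistency in image space followed by analysis-threshold-
        synthesis equals the coefficient-space ISTA update for an
        orthonormal wavelet (the linear special case of the composite loop)."""
        spec = ew.WaveletSpec("db1", 4)
        J, lam = 2.0, 10.0
        x = rng.uniform(0, 255, (64, 64))
        resid = kspace64.values - ew.apply_U(x, kspace64.mask)
        r = x + (2 / J) * np.real(ew.apply_U_adjoint(resid, kspace64.mask))
        image_route = dwt_inverse(
            dwt_forward(r, spec).copy_with(
                ew.shrink(dwt_forward(r, spec).array, 2 * lam / J)))
        a = dwt_forward(np.real(ew.apply_U_adjoint(kspace64.values, kspace64.mask)),
                        spec)
        omega = dwt_forward(x, spec)
        coeff_route = dwt_inverse(a.copy_with(ew.shrink(
            omega.array + (2 / J) * (a.array - _apply_A(omega, kspace64.mask)),
            2 * lam / J)))
        assert np.abs(image_route - coeff_route).max() <= 1e-10 * 255

    def test_early_stop_on_tolerance(self, phantom64):
        full = ew.make_mask((64, 64), 1.0)
        y = ew.forward_model(phantom64, full, 0.0)
        cfg = ew.SolverConfig(lam=1e-6, wavelet=ew.WaveletSpec("db1", 4),
                              ewt_k=1, shift_enabled=False, max_iter=100,
                              tol=1e-6)
        r = ew.ewistars_solve(y, cfg)
        assert r.iterations_run < 100
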