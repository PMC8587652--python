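"""Reassignment operators, streaming recursion, complexity instrumentation."""

import numpy as np
import pytest

from kcdetect.core import Signal
from kcdetect.reassign import (
    OpCounter,
    RecursionState,
    apply_reassign,
    count_reassign_ops,
    direct_streams,
    fast_hermitian_eval,
    full_sum_mult_count,
    modified_kernels,
    reassigned_spwvd,
    reassignment_operators,
    recursion_step_cost,
    recursive_modified_stream,
    recursive_spwvd_stream,
    recursive_streams,
)
from kcdetect.synth import make_chirp
from kcdetect.tfr import TFRGrid, KernelSpec
from kcdetect.windows import make_window

ADMISSIBLE = [
    ("rectangular", None),
    ("exponential", 0.94),
    ("half_sine", None),
    ("hamming", None),
    ("hanning", None),
]


def _window(name, half, alpha=None):
    if alpha is None:
        return make_window(name, 2 * half + 1)
    return make_window(name, 2 * half + 1, alpha=alpha)


class TestModifiedKernels:
    def test_time_kernel_vanishes_at_center_row(self):
        g, h = make_window("hamming", 17), make_window("hamming", 9)
        t_kernel, _ = modified_kernels(g, h)
        l = np.arange(-8, 9)
        assert np.all(t_kernel.evaluate(np.zeros_like(l), l) == 0)

    def test_lag_derivative_of_rectangular_is_boundary_impulses(self):
        g = make_window("rectangular", 17)
        h = make_window("hamming", 9)
        _, d_kernel = modified_kernels(g, h)
        dcoef = d_kernel.lag.coefficients
        assert np.all(dcoef[1:-1] == 0)
        assert dcoef[0] == 0.5 and dcoef[-1] == -0.5

    def test_half_lag_symmetries_for_hamming_windows(self):
        # lag-conjugation symmetry that enables the one-sided evaluation:
        # T is even in l (conjugate pairs), D is odd in l (anti-conjugate)
        g, h = make_window("hamming", 17), make_window("hamming", 9)
        t_kernel, d_kernel = modified_kernels(g, h)
        m = np.arange(-4, 5)
        for l in range(1, 9):
            lv = np.full_like(m, l)
            assert np.allclose(
                t_kernel.evaluate(m, -lv), np.conj(t_kernel.evaluate(m, lv))
            )
            assert np.allclose(
                d_kernel.evaluate(m, -lv), -np.conj(d_kernel.evaluate(m, lv))
            )
        # and time-conjugation symmetry of the D kernel (even time window)
        for l in range(-8, 9):
            lv = np.full_like(m, l)
            assert np.allclose(
                d_kernel.evaluate(-m, lv), np.conj(d_kernel.evaluate(m, lv))
            )

    def test_rejects_non_hermitian_time_window(self):
        g = make_window("hamming", 17)
        h = make_window("exponential", 9, alpha=0.9)
        with pytest.raises(ValueError, match="even"):
            modified_kernels(g, h)


class TestOperators:
    def test_tone_frequency_operator_within_half_bin(self, tone):
        sig, v0, k0, n_freq = tone
        g, h = make_window("hamming", 33), make_window("hamming", 17)
        C, C_T, C_D = direct_streams(sig, g, h, n_freq)
        fld = reassignment_operators(C, C_T, C_D)
        # near the ridge the estimate must localize the tone
        ridge = fld.v_hat[40:-40, k0 - 1 : k0 + 2]
        assert np.max(np.abs(ridge - v0)) <= 0.5 / (2 * n_freq)

    def test_impulse_time_operator_within_one_sample(self):
        imp = np.zeros(128, complex)
        imp[60] = 1.0
        sig = Signal(imp, 1.0)
        g, h = make_window("hamming", 33), make_window("hamming", 17)
        C, C_T, C_D = direct_streams(sig, g, h, 64)
        fld = reassignment_operators(C, C_T, C_D)
        assert np.max(np.abs(fld.n_hat[fld.valid] - 60)) <= 1.0

    def test_zero_modified_streams_give_identity_field(self, complex_noise):
        sig = Signal(complex_noise(64), 1.0)
        g, h = make_window("hamming", 17), make_window("hamming", 9)
        C, C_T, C_D = direct_streams(sig, g, h, 32)
        zero_T = TFRGrid(
            np.zeros_like(C_T.values), C.time_axis, C.freq_axis, C_T.kernel
        )
        zero_D = TFRGrid(
            np.zeros_like(C_D.values), C.time_axis, C.freq_axis, C_D.kernel
        )
        fld = reassignment_operators(C, zero_T, zero_D)
        assert np.allclose(fld.n_hat, np.arange(64)[:, None])
        assert np.allclose(fld.v_hat, C.freq_axis[None, :])


class TestApplyReassign:
    def test_identity_field_preserves_grid(self, complex_noise):
        sig = Signal(complex_noise(64), 1.0)
        g, h = make_window("hamming", 17), make_window("hamming", 9)
        C, C_T, C_D = direct_streams(sig, g, h, 32)
        zero = lambda grid: TFRGrid(
            np.zeros_like(grid.values), C.time_axis, C.freq_axis, grid.kernel
        )
        fld = reassignment_operators(C, zero(C_T), zero(C_D))
        out = apply_reassign(C, fld)
        assert np.allclose(out.values, C.values, atol=1e-12)

    def test_signed_total_conserved(self, complex_noise):
        sig = Signal(complex_noise(128), 1.0)
        g, h = make_window("hamming", 33), make_window("hamming", 9)
        out = reassigned_spwvd(sig, g, h, 64)
        C = direct_streams(sig, g, h, 64)[0]
        total = np.sum(np.real(C.values))
        assert abs(out.values.sum() - total) <= 1e-9 * abs(total)

    def test_tone_energy_concentrates_into_one_row(self):
        n_freq = 65
        k0 = 20
        v0 = k0 / (2 * n_freq)
        sig = Signal(np.exp(2j * np.pi * v0 * np.arange(1024)), 1.0)
        g, h = make_window("hamming", 65), make_window("hamming", 17)
        out = reassigned_spwvd(sig, g, h, n_freq)
        frac = np.abs(out.values[:, k0]).sum() / np.abs(out.values).sum()
        assert frac >= 0.95


class TestRecursion:
    @pytest.mark.parametrize("name,alpha", ADMISSIBLE)
    def test_streams_match_direct_oracle(self, name, alpha, rng):
        g = _window("hamming", 8)
        h = _window(name, 8, alpha)
        for trial in range(3):
            x = rng.standard_normal(128) + 1j * rng.standard_normal(128)
            sig = Signal(x, 1.0)
            D = direct_streams(sig, g, h, 32)
            R = recursive_streams(sig, g, h, 32)
            for d, r in zip(D, R):
                scale = np.max(np.abs(d.values))
                assert np.max(np.abs(d.values - r.values)) <= 1e-8 * scale

    def test_functional_stream_wrappers(self, complex_noise):
        g = make_window("hamming", 17)
        h = make_window("hanning", 9)
        sig = Signal(complex_noise(96), 1.0)
        state = RecursionState.from_window(h)
        C = recursive_spwvd_stream(sig, state, g, 32)
        C_T = recursive_modified_stream(sig, state, g, 32, "T")
        C_D = recursive_modified_stream(sig, state, g, 32, "D")
        D = direct_streams(sig, g, h, 32)
        for d, r in zip(D, (C, C_T, C_D)):
            assert np.max(np.abs(d.values - r.values)) <= 1e-8 * np.max(
                np.abs(d.values)
            )

    def test_no_time_smoothing_gives_zero_t_stream(self, complex_noise):
        g = make_window("hamming", 17)
        h = make_window("rectangular", 1)  # M = 0
        sig = Signal(complex_noise(64), 1.0)
        C_T = recursive_streams(sig, g, h, 32)[1]
        assert np.max(np.abs(C_T.values)) <= 1e-12

    def test_inadmissible_window_names_families(self, complex_noise):
        g = make_window("hamming", 17)
        h = make_window("bartlett", 9)
        sig = Signal(complex_noise(64), 1.0)
        with pytest.raises(ValueError, match="rectangular"):
            recursive_streams(sig, g, h, 32)

    def test_state_reconstruction_invariant(self):
        h = make_window("hanning", 17)
        state = RecursionState.from_window(h)
        m = h.support
        recon = sum(
            t.coefficient * t.ratio ** m.astype(float) for t in state.exp_terms
        )
        assert np.max(np.abs(recon - h.coefficients)) <= 1e-12

    def test_per_step_cost_independent_of_time_half_length(self):
        costs = [
            recursion_step_cost(make_window("hanning", 2 * M + 1), L=8)
            for M in (4, 8, 16, 32)
        ]
        assert all(c == costs[0] for c in costs)


class TestFastHermitian:
    def test_matches_full_double_sum_oracle(self, complex_noise):
        sig = Signal(complex_noise(64), 1.0)
        g, h = make_window("hamming", 17), make_window("hamming", 9)
        _, C_T, C_D = direct_streams(sig, g, h, 32)
        W_T, W_D = fast_hermitian_eval(sig, g, h, 32)
        assert np.max(np.abs(W_T - np.real(C_T.values))) <= 1e-10 * np.max(
            np.abs(C_T.values)
        )
        assert np.max(np.abs(W_D - C_D.values)) <= 1e-10 * np.max(
            np.abs(C_D.values)
        )

    def test_single_sample_signal_keeps_only_zero_lag(self):
        x = np.zeros(32, complex)
        x[16] = 2.0
        sig = Signal(x, 1.0)
        g, h = make_window("hamming", 9), make_window("hamming", 5)
        W_T, W_D = fast_hermitian_eval(sig, g, h, 16)
        # R[n, l] nonzero only at l = 0, n = 16; the T kernel weights it by
        # m * h[m] summed against the time offset, the D kernel by g'[0] = 0
        assert np.max(np.abs(W_D)) <= 1e-14
        expected_T = np.zeros((32, 16))
        for m in range(-2, 3):
            expected_T[16 - m, :] += m * h.coefficients[m + 2] * 4.0 * g.coefficients[4]
        assert np.allclose(W_T, expected_T, atol=1e-12)

    def test_halves_lag_loop_multiplications(self, complex_noise):
        sig = Signal(complex_noise(64), 1.0)
        g, h = make_window("hamming", 17), make_window("hamming", 9)
        counter = OpCounter()
        fast_hermitian_eval(sig, g, h, 32, counter=counter)
        full = full_sum_mult_count(g, 64, 32)
        assert counter.multiplications <= full // 2 + 2 * 64 * 32

    def test_rejects_uneven_time_window(self, complex_noise):
        sig = Signal(complex_noise(64), 1.0)
        g = make_window("hamming", 17)
        h = make_window("exponential", 9, alpha=0.9)
        with pytest.raises(ValueError, match="even"):
            fast_hermitian_eval(sig, g, h, 32)


class TestOpCounts:
    @pytest.mark.parametrize("n_freq", [16, 64, 256])
    def test_reallocation_cost_bounds(self, n_freq):
        adds, mults = count_reassign_ops(n_freq)
        assert adds <= 3 * n_freq
        assert mults <= 2 * n_freq

    def test_degenerate_single_bin_grid(self):
        adds, mults = count_reassign_ops(1)
        assert adds <= 3 and mults <= 2


class TestReassignedSPWVD:
    def test_direct_and_recursive_modes_agree(self, complex_noise):
        sig = Signal(complex_noise(128), 1.0)
        g, h = make_window("hamming", 17), make_window("hanning", 9)
        a = reassigned_spwvd(sig, g, h, 64, mode="direct")
        b = reassigned_spwvd(sig, g, h, 64, mode="recursive")
        assert np.max(np.abs(a.values - b.values)) <= 1e-8 * np.max(
            np.abs(a.values)
        )

    def test_chirp_ridge_tracks_linear_law(self):
        sig = make_chirp(512, 0.1, 0.3, analytic=True)
        g, h = make_window("hamming", 65), make_window("hamming", 65)
        grid = reassigned_spwvd(sig, g, h, 512)
        k = np.argmax(grid.values, axis=1)
        f = 0.1 + 0.2 * np.arange(512) / 511
        err = np.abs(k - np.round(f * 1024))[51:461]
        assert np.median(err) <= 1.0

    def test_zero_signal_gives_zero_grid(self):
        sig = Signal(np.zeros(64, complex), 1.0)
        g, h = make_window("hamming", 17), make_window("hamming", 9)
        out = reassigned_spwvd(sig, g, h, 32)
        assert np.all(out.values == 0)

    def test_unknown_mode_rejected(self, complex_noise):
        sig = Signal(complex_noise(64), 1.0)
        g, h = make_window("hamming", 17), make_window("hamming", 9)
        with pytest.raises(ValueError, match="mode"):
            reassigned_spwvd(sig, g, h, 32, mode="magic")
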