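"""Reassignment (reallocation) of pseudo-Wigner-Ville distributions and
its streaming recursive evaluation.

Reassignment sharpens a smoothed time-frequency distribution by moving the
value of every cell to a locally estimated center of gravity.  The
operators are ratios of *modified-kernel* distributions to the plain one:
with separable kernel Phi[m, l] = g[l] h[m] (lag window g, time window h),

    T*Phi[m, l] = m * g[l] * h[m]          (time-weighted kernel)
    D*Phi[m, l] = g'[l] * h[m]             (lag-derivative kernel)

and, under the e^{-j4 pi v l} convention of this package,

    n_hat = n + Re{ C[.; T*Phi] / C[.; Phi] }
    v_hat = v - (1/4pi) * Im{ C[.; D*Phi] / C[.; Phi] }.

The signs and scales above are fixed once by the impulse/tone calibration
(an impulse at n0 reassigns to n0, a tone at v0 to v0) and then frozen.

When the time window h decomposes into exponential components
h[m] = sum_k c_k rho_k^m on [-M, M], all three distributions admit a
first-order streaming recursion whose per-step cost is independent of M:

    S[n, l]   = a S[n-1, l] + c_in R[n+M, l] - c_out R[n-M-1, l]
    S_T[n, l] = a S_T[n-1, l] - S[n, l]
                + (M+1) c_in R[n+M, l] + M c_out R[n-M-1, l]

per component (a = 1/rho, c_in = c rho^M, c_out = c rho^-(M+1)), with the
D stream sharing the plain accumulator S and swapping the lag weights g
for g'.  The direct double-sum evaluation in :mod:`kcdetect.tfr` is the
reference oracle for every recursive path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Signal
from .tfr import (
    TFRGrid,
    KernelSpec,
    WIGNER_VILLE,
    _check_analytic,
    _freq_axis,
    _lag_transform,
    _maybe_real,
    autocorr_matrix,
    smoothed_pwvd,
    time_smooth,
)
from .windows import (
    RECURSIVE_FAMILIES,
    ExpTerm,
    Window,
    exp_decompose,
    window_derivative,
)

#: operator constants frozen by the impulse/tone calibration
TIME_SCALE = 1.0
FREQ_SCALE = -1.0 / (4.0 * np.pi)

#: validity floor, relative to max |C|
FLOOR_REL = 1e-12


# ---------------------------------------------------------------------------
# modified kernels


@dataclass
class SeparableKernel:
    """A separable time-lag kernel lag[l] * time[m]."""

    lag: Window
    time: Window

    def evaluate(self, m: np.ndarray, l: np.ndarray) -> np.ndarray:
        return self.lag(l) * self.time(m)


def _time_weighted(h: Window) -> Window:
    coeffs = h.support.astype(float) * h.coefficients
    return Window(h.name + "_t_weighted", coeffs, h.half_length)


def modified_kernels(g: Window, h: Window) -> tuple[SeparableKernel, SeparableKernel]:
    """T*Phi and D*Phi kernels for a Hermitian separable kernel g[l]h[m].

    The Hermitian symmetry (g[l]h[m])* = g[l]h[-m] requires a real,
    even time window; non-Hermitian inputs are rejected.  The D kernel
    differentiates the *lag* window (the lag is the variable conjugate to
    frequency, so its derivative produces the frequency operator).
    """
    if not (np.isrealobj(g.coefficients) and np.isrealobj(h.coefficients)):
        raise ValueError("windows must be real-valued")
    if not h.is_even(1e-9):
        raise ValueError("time window must be even (Hermitian kernel required)")
    t_kernel = SeparableKernel(g, _time_weighted(h))
    d_kernel = SeparableKernel(window_derivative(g), h)
    return t_kernel, d_kernel


# ---------------------------------------------------------------------------
# reassignment operators and application


@dataclass
class ReassignField:
    """Per-cell reassignment targets.

    ``n_hat`` and ``v_hat`` give the reassigned time index and normalized
    frequency; ``valid`` masks cells whose plain distribution magnitude
    exceeds the floor (operators are undefined where C vanishes).
    """

    n_hat: np.ndarray
    v_hat: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if not (self.n_hat.shape == self.v_hat.shape == self.valid.shape):
            raise ValueError("field component shapes must match")


def reassignment_operators(
    C: TFRGrid,
    C_T: TFRGrid,
    C_D: TFRGrid,
    floor_rel: float = FLOOR_REL,
) -> ReassignField:
    """Compute (n_hat, v_hat) from the plain and modified distributions."""
    if not (C.values.shape == C_T.values.shape == C_D.values.shape):
        raise ValueError("grids must share axes")
    base = np.real(C.values)
    peak = np.max(np.abs(base))
    floor = floor_rel * (peak if peak > 0 else 1.0)
    valid = np.abs(base) > floor
    n_grid = np.broadcast_to(
        np.asarray(C.time_axis, dtype=float)[:, None], base.shape
    ).copy()
    v_grid = np.broadcast_to(C.freq_axis[None, :], base.shape).copy()
    n_hat = n_grid.copy()
    v_hat = v_grid.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        rt = np.real(C_T.values) / base
        rd = np.imag(C_D.values) / base
    n_hat[valid] = n_grid[valid] + TIME_SCALE * rt[valid]
    v_hat[valid] = v_grid[valid] + FREQ_SCALE * rd[valid]
    return ReassignField(n_hat, v_hat, valid)


def apply_reassign(
    C: TFRGrid,
    fld: ReassignField,
    *,
    discard_offgrid: bool = False,
    magnitude: bool = False,
) -> TFRGrid:
    """Move each valid cell's value to the cell nearest (n_hat, v_hat).

    Out-of-range targets are clipped to the grid edge (default), which
    makes the signed total of the distribution an exact invariant of the
    operation; ``discard_offgrid=True`` drops them instead.  Invalid cells
    keep their value in place.
    """
    if fld.n_hat.shape != C.values.shape:
        raise ValueError("field shape must match the grid")
    vals = np.abs(C.values) if magnitude else np.real(C.values)
    n_t, n_f = vals.shape
    out = np.zeros_like(vals)
    tgt_n = np.rint(fld.n_hat).astype(int)
    tgt_k = np.rint(fld.v_hat * 2 * n_f).astype(int)
    if discard_offgrid:
        ongrid = (tgt_n >= 0) & (tgt_n < n_t) & (tgt_k >= 0) & (tgt_k < n_f)
        sel = fld.valid & ongrid
    else:
        tgt_n = np.clip(tgt_n, 0, n_t - 1)
        tgt_k = np.clip(tgt_k, 0, n_f - 1)
        sel = fld.valid
    np.add.at(out, (tgt_n[sel], tgt_k[sel]), vals[sel])
    out[~fld.valid] += vals[~fld.valid]
    spec = KernelSpec(
        C.kernel.id,
        sigma=C.kernel.sigma,
        lag_window=C.kernel.lag_window,
        time_window=C.kernel.time_window,
    )
    return TFRGrid(out, C.time_axis, C.freq_axis, spec, fs=C.fs)


# ---------------------------------------------------------------------------
# direct evaluation of the modified distributions


def direct_streams(
    x: Signal, g: Window, h: Window, n_freq: int
) -> tuple[TFRGrid, TFRGrid, TFRGrid]:
    """(C, C_T, C_D) by direct double-sum evaluation (the oracle path)."""
    C = smoothed_pwvd(x, g, h, n_freq)
    C_T = smoothed_pwvd(x, g, _time_weighted(h), n_freq, cast_real=False)
    C_D = smoothed_pwvd(x, window_derivative(g), h, n_freq, cast_real=False)
    return C, C_T, C_D


# ---------------------------------------------------------------------------
# streaming recursion


@dataclass
class RecursionState:
    """Exponential decomposition and geometry of the time window h.

    ``exp_terms`` holds (coefficient, ratio) pairs with
    h[m] = sum_k c_k rho_k^m exactly on [-M, M] (validated to 1e-12 at
    construction).  ``alpha`` is the forgetting factor of the one-term
    exponential family when applicable.
    """

    M: int
    exp_terms: list[ExpTerm]
    alpha: float | None = None
    c: float = 1.0
    window: Window | None = None

    @classmethod
    def from_window(cls, h: Window) -> "RecursionState":
        if h.name not in RECURSIVE_FAMILIES:
            raise ValueError(
                f"time window {h.name!r} is not admissible for the streaming "
                f"recursion; admissible families: {RECURSIVE_FAMILIES}"
            )
        terms = exp_decompose(h)
        return cls(
            M=h.half_length,
            exp_terms=terms,
            alpha=h.alpha,
            c=h.scale,
            window=h,
        )


class OpCounter:
    """Scalar operation counter for instrumented evaluations.

    Divisions are counted as multiplications; comparisons against the
    validity floor are counted as additions (a subtraction).
    """

    def __init__(self) -> None:
        self.additions = 0
        self.multiplications = 0

    def add(self, n: int = 1) -> None:
        self.additions += n

    def mul(self, n: int = 1) -> None:
        self.multiplications += n


def _stream_rows(
    samples: np.ndarray,
    state: RecursionState,
    L: int,
    counter: OpCounter | None = None,
    max_count_steps: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the per-lag recursions; return (S, S_T) rows for n = 0..N-1."""
    N = samples.size
    M = state.M
    R = autocorr_matrix(samples, L)
    width = 2 * L + 1
    pad_lo = M + 1
    Rpad = np.vstack(
        [np.zeros((pad_lo, width), complex), R, np.zeros((M, width), complex)]
    )

    def row(t: int) -> np.ndarray:
        return Rpad[t + pad_lo]

    terms = state.exp_terms
    consts = []
    for t in terms:
        rho = t.ratio
        consts.append(
            (
                1.0 / rho,  # a
                t.coefficient * rho**M,  # c_in
                t.coefficient * rho ** (-(M + 1)),  # c_out
            )
        )
    S_acc = [np.zeros(width, complex) for _ in terms]
    ST_acc = [np.zeros(width, complex) for _ in terms]
    S_rows = np.empty((N, width), complex)
    ST_rows = np.empty((N, width), complex)
    counted = 0
    for n in range(-M, N):
        instrument = counter is not None and n >= 0 and counted < max_count_steps
        R_in = row(n + M)
        R_out = row(n - M - 1)
        for k, (a, c_in, c_out) in enumerate(consts):
            S_new = a * S_acc[k] + c_in * R_in - c_out * R_out
            ST_acc[k] = (
                a * ST_acc[k]
                - S_new
                + ((M + 1) * c_in) * R_in
                + (M * c_out) * R_out
            )
            S_acc[k] = S_new
            if instrument:
                # per lag: 3 mults + 2 adds (S), 3 mults + 3 adds (S_T);
                # the (M+1)c_in / M c_out products are precomputed constants
                counter.mul(6 * width)
                counter.add(5 * width)
        if instrument:
            counted += 1
        if n >= 0:
            S_rows[n] = np.sum(S_acc, axis=0)
            ST_rows[n] = np.sum(ST_acc, axis=0)
            if instrument:
                counter.add(2 * (len(terms) - 1) * width)
    return S_rows, ST_rows


def recursive_streams(
    x: Signal,
    g: Window,
    h: Window,
    n_freq: int,
    state: RecursionState | None = None,
) -> tuple[TFRGrid, TFRGrid, TFRGrid]:
    """(C, C_T, C_D) via the streaming recursion.

    Equals :func:`direct_streams` on the full grid; the recursion merely
    reorganizes the time smoothing so each step touches only the two
    boundary autocorrelation rows.
    """
    if state is None:
        state = RecursionState.from_window(h)
    s = _check_analytic(x)
    L = g.half_length
    S_rows, ST_rows = _stream_rows(s, state, L)
    gd = window_derivative(g)
    axis = np.arange(s.size)
    base_spec = KernelSpec(WIGNER_VILLE, lag_window=g, time_window=h)
    C = TFRGrid(
        _maybe_real(_lag_transform(S_rows, g.coefficients, n_freq)),
        axis,
        _freq_axis(n_freq),
        base_spec,
        fs=x.fs,
    )
    spec_T = KernelSpec(WIGNER_VILLE, lag_window=g, time_window=h, modified="T")
    C_T = TFRGrid(
        _lag_transform(ST_rows, g.coefficients, n_freq),
        axis,
        _freq_axis(n_freq),
        spec_T,
        fs=x.fs,
    )
    spec_D = KernelSpec(WIGNER_VILLE, lag_window=g, time_window=h, modified="D")
    C_D = TFRGrid(
        _lag_transform(S_rows, gd.coefficients, n_freq),
        axis,
        _freq_axis(n_freq),
        spec_D,
        fs=x.fs,
    )
    return C, C_T, C_D


def recursive_spwvd_stream(
    x: Signal, state: RecursionState, g: Window, n_freq: int
) -> TFRGrid:
    """Streaming smoothed pseudo-WVD (plain kernel)."""
    h = state.window
    if h is None:
        raise ValueError("state must carry its source window")
    return recursive_streams(x, g, h, n_freq, state=state)[0]


def recursive_modified_stream(
    x: Signal, state: RecursionState, g: Window, n_freq: int, which: str
) -> TFRGrid:
    """Streaming evaluation of the T- or D-modified distribution."""
    if which not in ("T", "D"):
        raise ValueError("which must be 'T' or 'D'")
    h = state.window
    if h is None:
        raise ValueError("state must carry its source window")
    _, C_T, C_D = recursive_streams(x, g, h, n_freq, state=state)
    return C_T if which == "T" else C_D


def recursion_step_cost(h: Window, L: int) -> dict[str, int]:
    """Instrumented scalar-op cost of one streaming update step.

    Measured on a short random signal; the count depends on the number of
    exponential components and the lag support, never on the time
    half-length M - the boundary-feed structure of the recursion is what
    the instrumentation demonstrates.
    """
    rng = np.random.default_rng(0)
    n = 4 * (h.half_length + L) + 8
    s = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    counter = OpCounter()
    state = RecursionState.from_window(h)
    _stream_rows(s, state, L, counter=counter, max_count_steps=1)
    return {"additions": counter.additions, "multiplications": counter.multiplications}


# ---------------------------------------------------------------------------
# Hermitian fast forms


def fast_hermitian_eval(
    x: Signal, g: Window, h: Window, n_freq: int, counter: OpCounter | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(W_T, W_D) evaluated over nonnegative lags only.

    For a Hermitian separable kernel the negative-lag half of the double
    sum is the conjugate (T) or negative conjugate (D) of the positive
    half, so with Xi the l >= 0 partial transform:

        W_T = 2 Re{Xi_T} - (l = 0 term),   W_D = 2j Im{Xi_D}

    (the D kernel's l = 0 column vanishes with g').  Halves the lag-loop
    multiplication count relative to the full sum.
    """
    if not h.is_even(1e-9):
        raise ValueError("Hermitian fast form requires an even time window")
    s = _check_analytic(x)
    L = g.half_length
    R = autocorr_matrix(s, L)
    Rpos = R[:, L:]  # columns l = 0..L
    gd = window_derivative(g)
    S_T = time_smooth(Rpos, _time_weighted(h))
    S_D = time_smooth(Rpos, h)
    N = s.size
    k = np.arange(n_freq)
    l = np.arange(L + 1)
    phase = np.exp(-2j * np.pi * np.outer(l, k) / n_freq)  # (L+1, Nf)
    Xi_T = (S_T * g.coefficients[L:]) @ phase
    Xi_D = (S_D * gd.coefficients[L:]) @ phase
    if counter is not None:
        # per (n, k) cell: one weight product and one phase product per lag
        counter.mul(2 * (L + 1) * N * n_freq)
    l0_T = np.real(S_T[:, 0] * g.coefficients[L])
    l0_D = S_D[:, 0] * gd.coefficients[L]
    W_T = 2.0 * np.real(Xi_T) - l0_T[:, None]
    W_D = 2j * np.imag(Xi_D) - 1j * np.imag(l0_D)[:, None]
    return W_T, W_D


def full_sum_mult_count(g: Window, n_times: int, n_freq: int) -> int:
    """Lag-loop multiplication count of the full double-sided sum."""
    return 2 * (2 * g.half_length + 1) * n_times * n_freq


# ---------------------------------------------------------------------------
# instrumented reallocation-function evaluation


def _evaluate_operators_instrumented(
    n: float,
    C_row: np.ndarray,
    CT_row: np.ndarray,
    CD_row: np.ndarray,
    freqs: np.ndarray,
    floor: float,
    counter: OpCounter,
) -> tuple[np.ndarray, np.ndarray]:
    """Scalar-by-scalar reallocation-operator evaluation with op counting.

    The operator scales are folded into the modified streams beforehand,
    so each frequency bin costs at most 3 additions (validity compare and
    the two offsets) and 2 multiplications (the two divisions).
    """
    n_hat = np.empty(C_row.size)
    v_hat = np.empty(C_row.size)
    for k in range(C_row.size):
        c = C_row[k]
        counter.add()  # |c| - floor validity compare
        if not abs(c) > floor:
            n_hat[k] = n
            v_hat[k] = freqs[k]
            continue
        rt = CT_row[k].real / c
        counter.mul()
        n_hat[k] = n + rt
        counter.add()
        rd = CD_row[k].imag / c
        counter.mul()
        v_hat[k] = freqs[k] + rd
        counter.add()
    return n_hat, v_hat


def count_reassign_ops(n_freq: int) -> tuple[int, int]:
    """Exact per-time-step op counts of the reallocation-function evaluation.

    Builds the three distribution streams of a broadband test signal,
    evaluates the reassignment operators at one time index over ``n_freq``
    bins with an instrumented scalar loop, and returns (additions,
    multiplications).  Every bin of a broadband signal is valid, so the
    returned counts are the worst case: 3 additions and 2 multiplications
    per bin (divisions counted as multiplications, constant scales folded
    into the modified kernels).
    """
    rng = np.random.default_rng(12345)
    L = min(max(1, n_freq // 4), (n_freq - 1) // 2)
    M = 4
    N = 4 * (L + M)
    s = rng.standard_normal(N) + 1j * rng.standard_normal(N)
    from .windows import make_window

    g = make_window("hamming", 2 * L + 1)
    h = make_window("hamming", 2 * M + 1)
    sig = Signal(s, fs=1.0, is_analytic=False)
    C, C_T, C_D = direct_streams(sig, g, h, n_freq)
    row = N // 2
    base = np.real(C.values[row])
    floor = FLOOR_REL * np.max(np.abs(C.values))
    counter = OpCounter()
    _evaluate_operators_instrumented(
        float(row),
        base,
        TIME_SCALE * C_T.values[row],
        FREQ_SCALE * C_D.values[row],  # operator scale folded into the stream
        C.freq_axis,
        floor,
        counter,
    )
    return counter.additions, counter.multiplications


# ---------------------------------------------------------------------------
# end-to-end reassigned distribution


def reassigned_spwvd(
    x: Signal,
    g: Window,
    h: Window,
    n_freq: int,
    mode: str = "direct",
    *,
    magnitude: bool = False,
    discard_offgrid: bool = False,
) -> TFRGrid:
    """Reassigned smoothed pseudo-Wigner-Ville distribution.

    ``mode='direct'`` evaluates the three streams by the double sum;
    ``mode='recursive'`` uses the streaming recursion.  Both compositions
    agree on the full grid.
    """
    if mode == "direct":
        C, C_T, C_D = direct_streams(x, g, h, n_freq)
    elif mode == "recursive":
        C, C_T, C_D = recursive_streams(x, g, h, n_freq)
    else:
        raise ValueError("mode must be 'direct' or 'recursive'")
    fld = reassignment_operators(C, C_T, C_D)
    return apply_reassign(
        C, fld, discard_offgrid=discard_offgrid, magnitude=magnitude
    )
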