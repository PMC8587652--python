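"""Discrete Cohen-class time-frequency energy distributions.

All grids share one convention: a distribution value at time index ``n``
and frequency bin ``k`` corresponds to normalized frequency
``v_k = k/(2*Nf)``, ``k = 0..Nf-1``, i.e. the half-band [0, 0.5).  The
doubled exponent ``exp(-j*4*pi*v*l)`` of the discrete Wigner-Ville lag
transform makes an ``Nf``-point DFT over the lag variable span exactly that
half band, which is why analytic input signals are the default (a real
input aliases the bilinear product; callers get a warning).

The smoothed pseudo-Wigner-Ville distribution

    W[n, k] = sum_l g[l] sum_m h[m] R[n+m, l] exp(-j*2*pi*k*l/Nf),

with ``R[n, l] = x[n+l] * conj(x[n-l])`` the instantaneous autocorrelation,
lag window ``g`` and time window ``h``, is the workhorse: it doubles as the
direct evaluation oracle for the streaming recursion and, with modified
windows, yields the reassignment operator numerators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.signal import fftconvolve

from .core import Signal
from .windows import RECTANGULAR, Window, make_window

WIGNER_VILLE = "wigner_ville"
BORN_JORDAN = "born_jordan"
CHOI_WILLIAMS = "choi_williams"
ZAM = "zam"
SPECTROGRAM = "spectrogram"
KERNEL_IDS = (WIGNER_VILLE, BORN_JORDAN, CHOI_WILLIAMS, ZAM, SPECTROGRAM)

#: imaginary residue tolerated when casting a Hermitian-kernel grid to real
_REAL_TOL = 1e-10


@dataclass
class KernelSpec:
    """Identity and parameters of a Cohen-class kernel.

    ``modified`` selects the plain kernel Phi, its time-weighted variant
    T*Phi (m * Phi) or its lag-derivative variant D*Phi, the latter two
    being the numerator kernels of the reassignment operators.
    """

    id: str
    sigma: float | None = None
    lag_window: Window | None = None
    time_window: Window | None = None
    modified: Literal["none", "T", "D"] = "none"

    def __post_init__(self) -> None:
        if self.id not in KERNEL_IDS:
            raise ValueError(f"unknown kernel {self.id!r}; choose from {KERNEL_IDS}")
        if self.id == CHOI_WILLIAMS and (self.sigma is None or not self.sigma > 0):
            raise ValueError("choi_williams requires sigma > 0")


@dataclass
class TFRGrid:
    """A time x frequency matrix with axis metadata.

    ``values`` is real for unmodified Hermitian kernels and complex for the
    modified (T/D) kernels.  ``freq_axis`` holds normalized frequencies
    ``k/(2*Nf)`` strictly increasing in [0, 0.5).
    """

    values: np.ndarray
    time_axis: np.ndarray
    freq_axis: np.ndarray
    kernel: KernelSpec
    fs: float | None = None

    def __post_init__(self) -> None:
        if self.values.shape != (self.time_axis.size, self.freq_axis.size):
            raise ValueError("values shape must match (time, freq) axes")
        if self.freq_axis.size and (
            np.any(np.diff(self.freq_axis) <= 0)
            or self.freq_axis[0] < 0
            or self.freq_axis[-1] >= 0.5
        ):
            raise ValueError("freq_axis must be strictly increasing in [0, 0.5)")

    @property
    def n_freq(self) -> int:
        return self.freq_axis.size

    def total(self) -> float | complex:
        return self.values.sum()


def _freq_axis(n_freq: int) -> np.ndarray:
    return np.arange(n_freq) / (2.0 * n_freq)


def _check_analytic(x: Signal) -> np.ndarray:
    if not x.is_analytic and not np.iscomplexobj(x.samples):
        warnings.warn(
            "real-valued input to a Wigner-Ville distribution aliases the "
            "bilinear product; pass the analytic signal",
            stacklevel=3,
        )
    return np.asarray(x.samples, dtype=complex)


def inst_autocorr(x: Signal, n: int, lag: int) -> complex:
    """Instantaneous autocorrelation R_x[n, l] = x[n+l] * conj(x[n-l]).

    Indices outside the signal support contribute zero.  Satisfies the
    conjugate symmetry R_x[n, -l] = conj(R_x[n, l]).
    """
    s = np.asarray(x.samples)
    N = s.size
    i, j = n + lag, n - lag
    if not (0 <= i < N and 0 <= j < N):
        return 0.0 + 0.0j
    return complex(s[i] * np.conj(s[j]))


def autocorr_matrix(samples: np.ndarray, max_lag: int) -> np.ndarray:
    """R[n, l] for n = 0..N-1 (rows) and l = -L..L (columns), zero-padded."""
    s = np.asarray(samples, dtype=complex)
    N, L = s.size, max_lag
    pad = np.concatenate([np.zeros(L, complex), s, np.zeros(L, complex)])
    R = np.empty((N, 2 * L + 1), dtype=complex)
    for j, l in enumerate(range(-L, L + 1)):
        R[:, j] = pad[L + l : L + l + N] * np.conj(pad[L - l : L - l + N])
    return R


def _lag_transform(S: np.ndarray, g: np.ndarray, n_freq: int) -> np.ndarray:
    """sum_l g[l] S[n, l] exp(-j*2*pi*k*l/Nf) over columns l = -L..L."""
    L = (S.shape[1] - 1) // 2
    if n_freq < 2 * L + 1:
        raise ValueError(f"n_freq={n_freq} must cover the lag support {2 * L + 1}")
    buf = np.zeros((S.shape[0], n_freq), dtype=complex)
    for j, l in enumerate(range(-L, L + 1)):
        buf[:, l % n_freq] += g[j] * S[:, j]
    return np.fft.fft(buf, axis=1)


def _maybe_real(values: np.ndarray) -> np.ndarray:
    peak = np.max(np.abs(values)) or 1.0
    if np.max(np.abs(values.imag)) <= _REAL_TOL * peak:
        return values.real
    return values


def time_smooth(R: np.ndarray, h: Window) -> np.ndarray:
    """S[n, l] = sum_m h[m] R[n+m, l] (cross-correlation along time)."""
    M = h.half_length
    if M == 0:
        return R * h.coefficients[0]
    kern = h.coefficients[::-1].astype(complex)[:, None]
    full = fftconvolve(R, kern, mode="full", axes=0)
    return full[M : M + R.shape[0]]


def pseudo_wvd(x: Signal, g: Window, n_freq: int) -> TFRGrid:
    """Pseudo-Wigner-Ville distribution (lag window ``g``, no time smoothing)."""
    s = _check_analytic(x)
    R = autocorr_matrix(s, g.half_length)
    vals = _maybe_real(_lag_transform(R, g.coefficients, n_freq))
    spec = KernelSpec(WIGNER_VILLE, lag_window=g)
    return TFRGrid(vals, np.arange(s.size), _freq_axis(n_freq), spec, fs=x.fs)


def smoothed_pwvd(
    x: Signal,
    g: Window,
    h: Window,
    n_freq: int,
    *,
    cast_real: bool = True,
) -> TFRGrid:
    """Smoothed pseudo-Wigner-Ville distribution (direct evaluation).

    This double-sum evaluation is the reference oracle for the streaming
    recursion: time smoothing with ``h`` over ``m in [-M, M]`` followed by
    the windowed lag transform with ``g``.
    """
    s = _check_analytic(x)
    R = autocorr_matrix(s, g.half_length)
    S = time_smooth(R, h)
    vals = _lag_transform(S, g.coefficients, n_freq)
    if cast_real:
        vals = _maybe_real(vals)
    spec = KernelSpec(WIGNER_VILLE, lag_window=g, time_window=h)
    return TFRGrid(vals, np.arange(s.size), _freq_axis(n_freq), spec, fs=x.fs)


def stft_complex(samples: np.ndarray, h: Window, n_fft: int, hop: int = 1) -> np.ndarray:
    """Short-time Fourier transform X[n, k] = sum_m x[n+m] h[m] e^{-j2pi k m/n_fft}.

    Full band: k = 0..n_fft-1.  Frames are centered on each analysis time
    (zero padding outside the record).  With hop=1 and a signal that
    vanishes within half a window of the record edges, the exact Parseval
    identity  sum |X|^2 = n_fft * sum|h|^2 * sum|x|^2  holds (each sample
    then meets every window position).
    """
    s = np.asarray(samples, dtype=complex)
    P = h.half_length
    if n_fft < 2 * P + 1:
        raise ValueError("n_fft must cover the window support")
    pad = np.concatenate([np.zeros(P, complex), s, np.zeros(P, complex)])
    starts = np.arange(0, s.size, hop)
    frames = np.stack([pad[n : n + 2 * P + 1] for n in starts])
    frames = frames * h.coefficients
    # place m = -P..P at DFT indices m mod n_fft so the phase reference is m=0
    buf = np.zeros((frames.shape[0], n_fft), dtype=complex)
    for j, m in enumerate(range(-P, P + 1)):
        buf[:, m % n_fft] += frames[:, j]
    return np.fft.fft(buf, axis=1)


def stft_spectrogram(x: Signal, h: Window, n_freq: int, hop: int = 1) -> TFRGrid:
    """Spectrogram |STFT|^2 sampled on the Cohen half-band grid.

    The DFT length is ``2*n_freq`` so bins align with the Wigner-Ville
    frequency axis ``v_k = k/(2*n_freq)``; the retained half band carries
    all but window-leakage energy for analytic inputs.  Values are
    nonnegative by construction.
    """
    if hop < 1:
        raise ValueError("hop must be >= 1")
    X = stft_complex(np.asarray(x.samples), h, 2 * n_freq, hop)
    vals = np.abs(X[:, :n_freq]) ** 2
    spec = KernelSpec(SPECTROGRAM, time_window=h)
    times = np.arange(0, len(x.samples), hop)
    return TFRGrid(vals, times, _freq_axis(n_freq), spec, fs=x.fs)


def _born_jordan_smooth(R: np.ndarray) -> np.ndarray:
    """Per-lag uniform time average over |m| <= |l| with weight 1/(2|l|+1)."""
    L = (R.shape[1] - 1) // 2
    S = np.empty_like(R)
    for j, l in enumerate(range(-L, L + 1)):
        w = abs(l)
        if w == 0:
            S[:, j] = R[:, j]
        else:
            kern = np.full(2 * w + 1, 1.0 / (2 * w + 1), dtype=complex)
            S[:, j] = np.convolve(R[:, j], kern, mode="same")
    return S


def _choi_williams_smooth(R: np.ndarray, sigma: float) -> np.ndarray:
    """Per-lag Gaussian time smoothing, spread |l|/sigma, unit mass."""
    L = (R.shape[1] - 1) // 2
    S = np.empty_like(R)
    for j, l in enumerate(range(-L, L + 1)):
        if l == 0:
            S[:, j] = R[:, j]
            continue
        spread = abs(l) / sigma
        half = max(1, int(np.ceil(3 * spread)))
        m = np.arange(-half, half + 1)
        kern = np.exp(-0.5 * (m / spread) ** 2)
        kern = (kern / kern.sum()).astype(complex)
        S[:, j] = np.convolve(R[:, j], kern, mode="same")
    return S


def _zam_smooth(R: np.ndarray) -> np.ndarray:
    """Cone-kernel sum over |m| <= |l| (no normalization)."""
    L = (R.shape[1] - 1) // 2
    S = np.empty_like(R)
    for j, l in enumerate(range(-L, L + 1)):
        w = abs(l)
        if w == 0:
            S[:, j] = R[:, j]
        else:
            kern = np.ones(2 * w + 1, dtype=complex)
            S[:, j] = np.convolve(R[:, j], kern, mode="same")
    return S


def cohen_distribution(x: Signal, kernel: KernelSpec, n_freq: int) -> TFRGrid:
    """Evaluate any supported Cohen-class distribution on the shared grid.

    The smoothing geometry in the (time, lag) plane defines each member:
    Born-Jordan averages uniformly over the cone |m| <= |l|, Choi-Williams
    applies a per-lag Gaussian whose spread grows with |l|/sigma, the
    Zhao-Atlas-Marks kernel sums over the cone, and the spectrogram is the
    squared short-time transform.  ``kernel.modified`` other than "none" is
    only meaningful for the (pseudo) Wigner-Ville path and is handled by
    the reassignment module.
    """
    if kernel.modified != "none":
        raise ValueError(
            "modified kernels are supported for the pseudo-WVD only; "
            "use kcdetect.reassign"
        )
    if kernel.id == SPECTROGRAM:
        h = kernel.time_window or make_window("hamming", 2 * (n_freq // 4) + 1)
        return stft_spectrogram(x, h, n_freq)
    g = kernel.lag_window or make_window(RECTANGULAR, min(2 * (n_freq // 2) - 1, 65))
    if kernel.id == WIGNER_VILLE:
        if kernel.time_window is not None:
            return smoothed_pwvd(x, g, kernel.time_window, n_freq)
        return pseudo_wvd(x, g, n_freq)
    s = _check_analytic(x)
    R = autocorr_matrix(s, g.half_length)
    if kernel.id == BORN_JORDAN:
        S = _born_jordan_smooth(R)
    elif kernel.id == CHOI_WILLIAMS:
        S = _choi_williams_smooth(R, float(kernel.sigma))
    else:  # ZAM
        S = _zam_smooth(R)
    vals = _maybe_real(_lag_transform(S, g.coefficients, n_freq))
    return TFRGrid(vals, np.arange(s.size), _freq_axis(n_freq), kernel, fs=x.fs)
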