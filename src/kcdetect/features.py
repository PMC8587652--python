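"""Fixed-length feature vectors from time-frequency distributions.

A segment's reassigned distribution is summarized by (i) a bilinearly
resampled magnitude patch (default 16 x 16), optionally log-compressed and
z-scored per segment, and (ii) per-band energy fractions for the
physiologically meaningful bands (delta, theta, sigma/spindle).  The patch
preserves the time-frequency signature of the transient; the band
fractions capture the spectral balance that distinguishes the delta-heavy
K-complex from spindle bursts and background.

:class:`TFRFeatureExtractor` packages the whole chain (notch -> analytic
-> reassigned smoothed pseudo-WVD -> features) as a stateless
scikit-learn transformer over a matrix of raw segment waveforms, so it
composes directly with sklearn pipelines and the MLP classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .core import Signal
from .preprocess import analytic, notch50
from .reassign import reassigned_spwvd
from .tfr import TFRGrid
from .windows import Window, make_window


@dataclass
class FeatureSpec:
    """Shape and normalization of the feature vector."""

    patch_shape: tuple[int, int] = (16, 16)
    compression: bool = False  # log1p of magnitudes before z-scoring
    normalize: bool = True  # per-segment z-score of the patch
    band_edges_Hz: tuple[tuple[float, float], ...] = (
        (0.5, 4.0),  # delta
        (4.0, 8.0),  # theta
        (11.0, 16.0),  # sigma (spindle band)
    )

    def __post_init__(self) -> None:
        if min(self.patch_shape) < 2:
            raise ValueError("patch dimensions must be >= 2")

    @property
    def n_features(self) -> int:
        return self.patch_shape[0] * self.patch_shape[1] + len(self.band_edges_Hz)


def _bilinear_resize(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resample of a 2-D array onto a target shape."""
    nt, nf = a.shape
    interp = RegularGridInterpolator(
        (np.arange(nt), np.arange(nf)), a, method="linear"
    )
    ti = np.linspace(0, nt - 1, shape[0])
    fi = np.linspace(0, nf - 1, shape[1])
    TT, FF = np.meshgrid(ti, fi, indexing="ij")
    return interp(np.stack([TT.ravel(), FF.ravel()], axis=1)).reshape(shape)


def tfr_features(grid: TFRGrid, spec: FeatureSpec, fs: float) -> np.ndarray:
    """Feature vector (patch then band fractions) of one distribution.

    Band energy is the sum of |values| over the band's frequency rows; the
    fractions are guarded so an all-zero grid maps to the zero vector.
    Output length is ``spec.n_features`` regardless of grid size.
    """
    mag = np.abs(grid.values)
    total = float(mag.sum())
    patch = _bilinear_resize(mag, spec.patch_shape)
    if spec.compression:
        patch = np.log1p(patch)
    if spec.normalize:
        sd = patch.std()
        patch = (patch - patch.mean()) / sd if sd > 1e-300 else np.zeros_like(patch)
    fracs = np.zeros(len(spec.band_edges_Hz))
    if total > 0:
        freqs_Hz = grid.freq_axis * fs
        for i, (lo, hi) in enumerate(spec.band_edges_Hz):
            rows = (freqs_Hz >= lo) & (freqs_Hz < hi)
            fracs[i] = float(mag[:, rows].sum()) / total
    out = np.concatenate([patch.ravel(), fracs])
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite feature values")
    return out


class TFRFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer: raw segment waveforms -> TFR features.

    Each row of X is one fixed-length segment in microvolts sampled at
    ``fs``.  The chain per segment: optional 50 Hz notch, analytic signal,
    reassigned smoothed pseudo-Wigner-Ville distribution (Hamming lag and
    time windows), then :func:`tfr_features`.

    Parameters
    ----------
    fs : sampling rate of the segment rows (Hz).
    n_freq : frequency bins of the distribution.
    lag_half, time_half : window half-lengths (L, M).
    notch : apply the 50 Hz notch before analysis.
    reassign_mode : 'direct' or 'recursive' stream evaluation.
    spec : FeatureSpec (built from defaults when None).
    """

    def __init__(
        self,
        fs: float = 200.0,
        n_freq: int = 64,
        lag_half: int = 16,
        time_half: int = 8,
        notch: bool = True,
        reassign_mode: str = "direct",
        spec: FeatureSpec | None = None,
    ):
        self.fs = fs
        self.n_freq = n_freq
        self.lag_half = lag_half
        self.time_half = time_half
        self.notch = notch
        self.reassign_mode = reassign_mode
        self.spec = spec

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=2)
        self.n_features_in_ = X.shape[1]
        self.spec_ = self.spec or FeatureSpec()
        self._g = make_window("hamming", 2 * self.lag_half + 1)
        self._h = make_window("hamming", 2 * self.time_half + 1)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "spec_")
        X = check_array(X)
        out = np.empty((X.shape[0], self.spec_.n_features))
        for i, row in enumerate(X):
            out[i] = self._features_of_segment(row)
        return out

    def _features_of_segment(self, row: np.ndarray) -> np.ndarray:
        sig = Signal(np.asarray(row, dtype=float), fs=self.fs)
        if self.notch:
            sig = notch50(sig)
        z = analytic(sig)
        grid = reassigned_spwvd(
            z, self._g, self._h, self.n_freq, mode=self.reassign_mode
        )
        return tfr_features(grid, self.spec_, self.fs)

    def segment_features(self, signal: Signal) -> np.ndarray:
        """Features of one already-cut segment given as a Signal."""
        if signal.fs != self.fs:
            raise ValueError(f"expected fs={self.fs}, got {signal.fs}")
        check_is_fitted(self, "spec_")
        return self._features_of_segment(np.real(signal.samples))
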