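"""Preprocessing: mains notch filtering, analytic signals, segmentation.

The acquisition chain superimposes 50 Hz interference from the supply
network on the EEG; a second-order IIR notch (pole-zero pair on the unit
circle at the mains frequency) removes it.  IIR is preferred over FIR here
for its shorter response time - the discriminative information lives in
the frequency content, not the phase.  The analytic form (no
negative-frequency content) is what the Wigner-Ville machinery consumes,
and fixed-length sliding windows with an overlap-based labeling rule turn
an annotated recording into a classification dataset.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.signal import filtfilt, hilbert, iirnotch, lfilter

from .core import KCOMPLEX, EventList, Signal, overlap_seconds
from .synth import SegmentDataset


def notch50(
    signal: Signal,
    f0: float = 50.0,
    bandwidth: float = 2.0,
    *,
    zero_phase: bool = False,
) -> Signal:
    """Second-order IIR notch at ``f0`` Hz (-3 dB width ``bandwidth``).

    Causal by default, matching an online acquisition chain;
    ``zero_phase=True`` applies the filter forward-backward instead.
    """
    if f0 >= signal.fs / 2:
        raise ValueError(f"notch frequency {f0} must lie below Nyquist {signal.fs / 2}")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    b, a = iirnotch(f0, f0 / bandwidth, fs=signal.fs)
    if zero_phase:
        y = filtfilt(b, a, signal.samples)
    else:
        y = lfilter(b, a, signal.samples)
    return Signal(y, fs=signal.fs, is_analytic=False)


def analytic(signal: Signal) -> Signal:
    """Analytic signal via the discrete Hilbert transform.

    The real part equals the input exactly and the spectrum carries no
    negative-frequency mass.  Passing an already-analytic signal is a
    no-op (with a warning).
    """
    if np.iscomplexobj(signal.samples):
        warnings.warn("input is already complex; returning it unchanged", stacklevel=2)
        return Signal(signal.samples.copy(), fs=signal.fs, is_analytic=signal.is_analytic)
    z = hilbert(signal.samples)
    return Signal(z, fs=signal.fs, is_analytic=True)


def segment_starts(n_samples: int, win_n: int, hop_n: int) -> np.ndarray:
    """Start indices of sliding windows fully inside the record."""
    if win_n > n_samples:
        return np.array([], dtype=int)
    return np.arange(0, n_samples - win_n + 1, hop_n)


def segment(
    signal: Signal,
    events: EventList | None = None,
    win_s: float = 2.0,
    hop_s: float = 0.5,
    min_overlap: float = 0.5,
) -> SegmentDataset:
    """Cut sliding fixed-length windows and label them.

    A window is positive iff some K-complex event overlaps it by at least
    ``min_overlap`` of the *event's* duration.  With hop <= win every
    sample of the record belongs to at least one window.
    """
    fs = signal.fs
    win_n = int(round(win_s * fs))
    hop_n = max(1, int(round(hop_s * fs)))
    if win_n < 2:
        raise ValueError("window must span at least 2 samples")
    starts = segment_starts(len(signal), win_n, hop_n)
    if starts.size == 0:
        warnings.warn("window longer than the record; empty dataset", stacklevel=2)
        return SegmentDataset(
            np.empty((0, win_n), dtype=signal.samples.dtype),
            np.empty(0, dtype=int),
            pd.DataFrame(columns=["record_id", "start_s", "fs"]),
        )
    X = np.stack([signal.samples[s : s + win_n] for s in starts])
    y = np.zeros(starts.size, dtype=int)
    if events is not None:
        kcs = [e for e in events if e.label == KCOMPLEX]
        for i, s in enumerate(starts):
            w0, w1 = s / fs, (s + win_n) / fs
            for e in kcs:
                if overlap_seconds(w0, w1, e.onset_s, e.end_s) >= min_overlap * e.duration_s:
                    y[i] = 1
                    break
    meta = pd.DataFrame({"record_id": 0, "start_s": starts / fs, "fs": fs})
    return SegmentDataset(X, y, meta)
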