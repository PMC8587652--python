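"""Synthetic stage-2 sleep EEG with annotated K-complexes and spindles.

The generator emulates the statistical structure of stage-2 sleep EEG as
scored in polysomnography: a band-limited background, delta-band activity
(1.6-4.0 Hz), a 0.8 Hz slow-wave component, 50 Hz mains interference, and
transient events - K-complexes (sharp negative peak exceeding 100 uV, a
positive lobe peaking 350-550 ms after onset, ~900 ms total) recurring
roughly every 1.0-1.7 min, each followed by a ~13 Hz sleep spindle with
probability one half.  Every inserted event is recorded in an
:class:`~kcdetect.core.EventList`, so downstream stages are testable with
no external data.

It also provides the linear-chirp test signal used to exercise the
time-frequency machinery: 512 samples, unit amplitude, normalized
frequency rising linearly from 0.1 to 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, sosfiltfilt

from .core import KCOMPLEX, SPINDLE, Event, EventList, Signal, overlap_seconds


def make_chirp(
    n_samples: int,
    f0: float,
    f1: float,
    amplitude: float = 1.0,
    *,
    analytic: bool = False,
) -> Signal:
    """Linear-FM test signal with normalized frequency f0 -> f1.

    The instantaneous normalized frequency at sample k is
    ``f0 + (f1 - f0) * k / (n_samples - 1)`` and the phase is the
    cumulative sum of the instantaneous frequency.  ``analytic=True``
    returns the analytic form (discrete Hilbert transform of the real
    chirp, which has exactly zero negative-frequency bins; the bare
    complex exponential would leak ~1e-3 of its energy below zero through
    the edge discontinuities).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    for f in (f0, f1):
        if not (0 <= f < 0.5):
            raise ValueError(f"normalized frequency {f} outside [0, 0.5)")
    k = np.arange(n_samples)
    finst = f0 + (f1 - f0) * k / (n_samples - 1)
    phase = 2 * np.pi * np.cumsum(finst)
    if analytic:
        from scipy.signal import hilbert

        return Signal(
            amplitude * hilbert(np.cos(phase)), fs=1.0, is_analytic=True
        )
    return Signal(amplitude * np.cos(phase), fs=1.0)


def kcomplex_template(
    fs: float,
    neg_peak_uV: float = 120.0,
    pos_latency_ms: float = 450.0,
    total_ms: float = 900.0,
    neg_latency_ms: float = 80.0,
    pos_fraction: float = 0.6,
) -> Signal:
    """Biphasic K-complex waveform built from a monotone landmark spline.

    The morphology is pinned at four landmarks: baseline at onset, the
    sharp negative peak of ``-neg_peak_uV`` at ``neg_latency_ms``, a
    positive lobe of ``pos_fraction * neg_peak_uV`` at ``pos_latency_ms``,
    and a return to baseline at ``total_ms``.  A clamped monotone (PCHIP)
    spline through the landmarks gives a smooth wave with no overshoot
    beyond the specified peaks.
    """
    if total_ms <= 0 or not (0 < pos_latency_ms < total_ms):
        raise ValueError("need 0 < pos_latency_ms < total_ms")
    if not (0 < neg_latency_ms < pos_latency_ms):
        raise ValueError("need 0 < neg_latency_ms < pos_latency_ms")
    n = int(round(total_ms * fs / 1000.0))
    t_ms = np.arange(n) / fs * 1000.0
    landmarks_t = np.array([0.0, neg_latency_ms, pos_latency_ms, total_ms])
    landmarks_v = np.array(
        [0.0, -neg_peak_uV, pos_fraction * neg_peak_uV, 0.0]
    )
    if np.all(landmarks_v == 0):
        return Signal(np.zeros(n), fs=fs)
    spline = PchipInterpolator(landmarks_t, landmarks_v)
    return Signal(spline(t_ms), fs=fs)


def spindle_template(
    fs: float, freq: float = 13.0, dur_s: float = 1.0, amplitude_uV: float = 1.0
) -> Signal:
    """Gaussian-enveloped sinusoid (a sleep-spindle burst)."""
    if not (0 < freq < fs / 2):
        raise ValueError(f"spindle frequency {freq} must lie below Nyquist {fs / 2}")
    if dur_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(dur_s * fs))
    t = np.arange(n) / fs
    center = (n - 1) / (2 * fs)
    envelope = np.exp(-0.5 * ((t - center) / (dur_s / 6.0)) ** 2)
    return Signal(amplitude_uV * envelope * np.sin(2 * np.pi * freq * t), fs=fs)


@dataclass
class SynthConfig:
    """Generation parameters (defaults encode stage-2 sleep morphology)."""

    duration_s: float = 1620.0
    fs: float = 200.0
    kc_interval_range_s: tuple[float, float] = (60.0, 102.0)
    kc_neg_peak_uV: float = 120.0
    kc_pos_latency_ms: tuple[float, float] = (350.0, 550.0)
    kc_total_ms: float = 900.0
    spindle_freq_Hz: float = 13.0
    spindle_follow_prob: float = 0.5
    spindle_dur_s: tuple[float, float] = (0.7, 1.2)
    spindle_amp_uV: float = 25.0
    delta_band_Hz: tuple[float, float] = (1.6, 4.0)
    delta_amp_uV: float = 20.0
    slow_wave_Hz: float = 0.8
    slow_wave_amp_uV: float = 20.0
    mains_Hz: float = 50.0
    mains_amp_uV: float = 10.0
    noise_band_Hz: tuple[float, float] = (0.5, 30.0)
    noise_rms_uV: float = 15.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be positive")
        lo, hi = self.kc_interval_range_s
        if not (0 < lo <= hi):
            raise ValueError("kc_interval_range_s must be an increasing positive pair")
        if not (0 <= self.spindle_follow_prob <= 1):
            raise ValueError("spindle_follow_prob must lie in [0, 1]")


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float], rms: float
) -> np.ndarray:
    if rms == 0:
        return np.zeros(n)
    lo, hi = band
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    sd = np.std(x)
    return x * (rms / sd) if sd > 0 else x


def synth_record(cfg: SynthConfig) -> tuple[Signal, EventList]:
    """Generate one annotated synthetic recording.

    The background is band-limited noise plus the delta-band component,
    the 0.8 Hz slow wave and the 50 Hz mains sinusoid; K-complex onsets
    follow a renewal process with inter-onset intervals uniform on
    ``kc_interval_range_s``, and each K-complex is followed by a spindle
    with probability ``spindle_follow_prob``.  Identical configs (seed
    included) give bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    x = _bandlimited_noise(rng, n, cfg.fs, cfg.noise_band_Hz, cfg.noise_rms_uV)
    x += _bandlimited_noise(rng, n, cfg.fs, cfg.delta_band_Hz, cfg.delta_amp_uV)
    x += cfg.slow_wave_amp_uV * np.sin(
        2 * np.pi * cfg.slow_wave_Hz * t + rng.uniform(0, 2 * np.pi)
    )
    x += cfg.mains_amp_uV * np.sin(
        2 * np.pi * cfg.mains_Hz * t + rng.uniform(0, 2 * np.pi)
    )

    events: list[Event] = []
    kc_dur = cfg.kc_total_ms / 1000.0
    onset = rng.uniform(*cfg.kc_interval_range_s)
    while onset + kc_dur < cfg.duration_s:
        latency = rng.uniform(*cfg.kc_pos_latency_ms)
        tpl = kcomplex_template(
            cfg.fs, cfg.kc_neg_peak_uV, latency, cfg.kc_total_ms
        )
        i0 = int(round(onset * cfg.fs))
        seg = tpl.samples[: n - i0]
        x[i0 : i0 + seg.size] += seg
        events.append(Event(onset, kc_dur, KCOMPLEX))
        if rng.uniform() < cfg.spindle_follow_prob:
            sp_dur = rng.uniform(*cfg.spindle_dur_s)
            sp_onset = onset + kc_dur + rng.uniform(0.2, 0.5)
            if sp_onset + sp_dur < cfg.duration_s:
                sp = spindle_template(
                    cfg.fs, cfg.spindle_freq_Hz, sp_dur, cfg.spindle_amp_uV
                )
                j0 = int(round(sp_onset * cfg.fs))
                spseg = sp.samples[: n - j0]
                x[j0 : j0 + spseg.size] += spseg
                events.append(Event(sp_onset, sp_dur, SPINDLE))
        onset += rng.uniform(*cfg.kc_interval_range_s)

    ev = EventList(sorted(events, key=lambda e: e.onset_s))
    ev.validate_within(cfg.duration_s)
    return Signal(x, fs=cfg.fs), ev


@dataclass
class SegmentDataset:
    """Fixed-length labeled segments (rows of X) with per-segment metadata."""

    X: np.ndarray
    y: np.ndarray
    meta: "object" = None  # pandas DataFrame: record_id, start_s, fs

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y must have equal row counts")
        if self.y.size and not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be 0/1")

    def __len__(self) -> int:
        return self.X.shape[0]


def make_dataset(
    cfg: SynthConfig,
    n_segments: int,
    pos_fraction: float,
    seed: int | None = None,
    *,
    win_s: float = 2.0,
    min_overlap: float = 0.5,
) -> SegmentDataset:
    """Balanced fixed-length segment dataset from one synthetic recording.

    Positive segments are windows containing a K-complex (overlap of at
    least ``min_overlap`` of the event duration, the same labeling rule as
    :func:`kcdetect.preprocess.segment`); negatives are windows with no
    K-complex overlap at all.  Raises if the record cannot supply the
    requested number of positives.
    """
    import pandas as pd

    if not (0 < pos_fraction < 1):
        raise ValueError("pos_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    record_cfg = replace(cfg, seed=int(rng.integers(2**31)))
    sig, events = synth_record(record_cfg)
    kcs = events.of_label(KCOMPLEX).events
    n_pos = int(round(n_segments * pos_fraction))
    n_neg = n_segments - n_pos
    if n_pos > len(kcs):
        raise ValueError(
            f"requested {n_pos} positive segments but the record contains "
            f"only {len(kcs)} K-complexes; increase cfg.duration_s"
        )
    win_n = int(round(win_s * cfg.fs))
    fs = cfg.fs
    rows, labels, starts = [], [], []
    order = rng.permutation(len(kcs))[:n_pos]
    for idx in order:
        e = kcs[idx]
        center = e.onset_s + e.duration_s / 2
        jitter = rng.uniform(-0.2, 0.2)
        start = np.clip(center - win_s / 2 + jitter, 0, sig.duration_s - win_s)
        i0 = int(round(start * fs))
        rows.append(sig.samples[i0 : i0 + win_n])
        labels.append(1)
        starts.append(i0 / fs)
    spans = [(e.onset_s, e.end_s) for e in kcs]
    attempts = 0
    while len(rows) < n_segments:
        attempts += 1
        if attempts > 200 * n_segments:
            raise ValueError("could not place enough K-complex-free segments")
        start = rng.uniform(0, sig.duration_s - win_s)
        if any(overlap_seconds(start, start + win_s, a, b) > 0 for a, b in spans):
            continue
        i0 = int(round(start * fs))
        rows.append(sig.samples[i0 : i0 + win_n])
        labels.append(0)
        starts.append(i0 / fs)
    perm = rng.permutation(n_segments)
    X = np.asarray(rows)[perm]
    y = np.asarray(labels)[perm]
    meta = pd.DataFrame(
        {
            "record_id": 0,
            "start_s": np.asarray(starts)[perm],
            "fs": fs,
        }
    )
    assert n_neg == int(np.sum(y == 0))
    return SegmentDataset(X, y, meta)
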