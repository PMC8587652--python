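"""Core containers: sampled signals and event annotations.

A :class:`Signal` is a uniformly sampled single-channel amplitude sequence
(microvolts for EEG, dimensionless for test signals) together with its
sampling rate.  Signals may be real or analytic (complex, with no
negative-frequency content); the analytic form is the default input to the
discrete Wigner-Ville machinery because it suppresses aliasing of the
bilinear product.

An :class:`EventList` holds ground-truth or detected annotations as
(onset, duration, label) triples in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

KCOMPLEX = "kcomplex"
SPINDLE = "spindle"
_VALID_LABELS = (KCOMPLEX, SPINDLE)


@dataclass
class Signal:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    samples : ndarray
        Amplitude sequence.  Real for raw recordings, complex for analytic
        signals.
    fs : float
        Sampling rate in Hz (must be positive).
    is_analytic : bool
        True when ``samples`` is complex with (numerically) no
        negative-frequency spectral mass.
    """

    samples: np.ndarray
    fs: float
    is_analytic: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.is_analytic:
            if not np.iscomplexobj(self.samples):
                raise ValueError("analytic signals must be complex-valued")
            frac = negative_frequency_fraction(self.samples)
            if frac > 1e-8:
                raise ValueError(
                    "analytic flag set but negative-frequency mass is "
                    f"{frac:.2e} of total (limit 1e-8)"
                )

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


def negative_frequency_fraction(x: np.ndarray) -> float:
    """Fraction of spectral energy at strictly negative frequencies."""
    X = np.fft.fft(np.asarray(x))
    total = float(np.sum(np.abs(X) ** 2))
    if total == 0.0:
        return 0.0
    n = X.size
    # bins n//2+1 .. n-1 are strictly negative frequencies; for even n the
    # shared Nyquist bin counts as non-negative
    neg = float(np.sum(np.abs(X[n // 2 + 1:]) ** 2))
    return neg / total


@dataclass
class Event:
    onset_s: float
    duration_s: float
    label: str

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("event duration must be positive")
        if self.label not in _VALID_LABELS:
            raise ValueError(f"label must be one of {_VALID_LABELS}")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class EventList:
    """Ordered event annotations (onsets nondecreasing)."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        onsets = [e.onset_s for e in self.events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be nondecreasing")

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def of_label(self, label: str) -> "EventList":
        return EventList([e for e in self.events if e.label == label])

    def onsets(self) -> np.ndarray:
        return np.array([e.onset_s for e in self.events])

    def validate_within(self, duration_s: float) -> None:
        for e in self.events:
            if e.onset_s < 0 or e.end_s > duration_s + 1e-9:
                raise ValueError(
                    f"event {e} lies outside the recording [0, {duration_s}]"
                )


def overlap_seconds(a_start: float, a_end: float, b_start: float, b_end: float) -> float:
    """Length of the intersection of two intervals (0 if disjoint)."""
    return max(0.0, min(a_end, b_end) - max(a_start, b_start))
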