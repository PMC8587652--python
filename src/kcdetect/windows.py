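"""Analysis windows for time-frequency kernels.

Windows here are symmetric-support sequences ``w[m]`` on ``m = -P..P``
(odd length ``2P+1``).  Two roles appear throughout the package: the *lag*
window ``g`` (frequency smoothing of the pseudo-Wigner-Ville distribution)
and the *time* window ``h`` (time smoothing).  The streaming recursion
requires ``h`` to decompose exactly into exponential components
``h[m] = sum_k c_k * rho_k**m`` on its support; the cosine families
(half-sine, Hamming, Hanning, Blackman), the rectangular window and the
one-term exponential window all admit such a decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RECTANGULAR = "rectangular"
HAMMING = "hamming"
HANNING = "hanning"
BLACKMAN = "blackman"
BARTLETT = "bartlett"
HALF_SINE = "half_sine"
EXPONENTIAL = "exponential"

WINDOW_NAMES = (
    RECTANGULAR,
    HAMMING,
    HANNING,
    BLACKMAN,
    BARTLETT,
    HALF_SINE,
    EXPONENTIAL,
)

#: cosine-series coefficients a_j of w[m] = sum_j a_j cos(j*pi*m/P)
_COSINE_SERIES = {
    HAMMING: (0.54, 0.46),
    HANNING: (0.5, 0.5),
    BLACKMAN: (0.42, 0.5, 0.08),
}

#: window families that admit an exact exponential decomposition on [-P, P]
RECURSIVE_FAMILIES = (RECTANGULAR, EXPONENTIAL, HALF_SINE, HAMMING, HANNING, BLACKMAN)


@dataclass
class Window:
    """A finite symmetric-support window.

    Attributes
    ----------
    name : str
        Family name.
    coefficients : ndarray
        Values ``w[-P..P]`` stored in increasing ``m`` (length ``2P+1``).
    half_length : int
        Support half-length ``P``.
    alpha : float or None
        Decay constant of the exponential family (``w[m] = c*alpha**(-m)``).
    """

    name: str
    coefficients: np.ndarray
    half_length: int
    alpha: float | None = None
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size != 2 * self.half_length + 1:
            raise ValueError("coefficient length must be 2*half_length+1")

    def __len__(self) -> int:
        return self.coefficients.size

    def __call__(self, m: int | np.ndarray) -> np.ndarray:
        """Evaluate w[m] with zero outside the support."""
        m = np.asarray(m)
        out = np.zeros(m.shape, dtype=float)
        inside = np.abs(m) <= self.half_length
        out[inside] = self.coefficients[m[inside] + self.half_length]
        return out

    @property
    def support(self) -> np.ndarray:
        return np.arange(-self.half_length, self.half_length + 1)

    def is_even(self, tol: float = 1e-12) -> bool:
        return bool(np.max(np.abs(self.coefficients - self.coefficients[::-1])) <= tol)


def make_window(name: str, length: int, alpha: float = 0.94, scale: float = 1.0) -> Window:
    """Construct a named window of odd ``length`` = 2P+1.

    Coefficients follow the standard closed forms of each family written on
    the centered index ``m in [-P, P]`` (the periodic-symmetric convention,
    so e.g. a Hamming endpoint is exactly 0.54-0.46 = 0.08).  The
    ``exponential`` family is ``w[m] = scale * alpha**(-m)`` - the forgetting
    window that makes the time-smoothing recursion first order.
    """
    if name not in WINDOW_NAMES:
        raise ValueError(f"unknown window {name!r}; choose from {WINDOW_NAMES}")
    if length < 1 or length % 2 == 0:
        raise ValueError("window length must be a positive odd integer")
    P = (length - 1) // 2
    m = np.arange(-P, P + 1)
    if name == RECTANGULAR:
        w = np.ones(length)
    elif name == BARTLETT:
        w = 1.0 - np.abs(m) / P if P > 0 else np.ones(1)
    elif name == HALF_SINE:
        w = np.cos(np.pi * m / length)
    elif name == EXPONENTIAL:
        if not alpha > 0:
            raise ValueError("alpha must be positive")
        w = scale * alpha ** (-m.astype(float))
        return Window(name, w, P, alpha=alpha, scale=scale)
    else:
        coeffs = _COSINE_SERIES[name]
        w = np.zeros(length)
        if P == 0:
            w[:] = sum(coeffs)
        else:
            for j, a in enumerate(coeffs):
                w += a * np.cos(j * np.pi * m / P)
    return Window(name, w, P)


def window_derivative(win: Window) -> Window:
    """Derivative dw/dm of a window, evaluated on its support.

    Cosine families use the analytic derivative of their closed form;
    tabulated families (rectangular, bartlett, exponential) fall back to
    central differences with zero extension, which for the rectangular
    window leaves zeros in the interior and half-height impulses at the
    edges.
    """
    P = win.half_length
    m = np.arange(-P, P + 1)
    if win.name in _COSINE_SERIES and P > 0:
        d = np.zeros(2 * P + 1)
        for j, a in enumerate(_COSINE_SERIES[win.name]):
            d += -a * (j * np.pi / P) * np.sin(j * np.pi * m / P)
    elif win.name == HALF_SINE:
        d = -(np.pi / len(win)) * np.sin(np.pi * m / len(win))
    else:
        padded = np.concatenate([[0.0], win.coefficients, [0.0]])
        d = (padded[2:] - padded[:-2]) / 2.0
    return Window(win.name + "_derivative", d, P)  # type: ignore[arg-type]


@dataclass
class ExpTerm:
    """One exponential component c * rho**m of a time window."""

    coefficient: complex
    ratio: complex


def exp_decompose(win: Window, tol: float = 1e-12) -> list[ExpTerm]:
    """Exact exponential decomposition h[m] = sum_k c_k rho_k**m on [-P, P].

    Raises ``ValueError`` for window families outside the admissible class
    (the recursion needs every component to obey a first-order shift rule).
    The reconstruction is validated to ``tol`` before returning.
    """
    P = win.half_length
    if win.name == RECTANGULAR:
        terms = [ExpTerm(1.0 + 0j, 1.0 + 0j)]
    elif win.name == EXPONENTIAL:
        terms = [ExpTerm(complex(win.scale), complex(1.0 / win.alpha))]
    elif win.name == HALF_SINE:
        theta = np.pi / len(win)
        terms = [
            ExpTerm(0.5 + 0j, np.exp(1j * theta)),
            ExpTerm(0.5 + 0j, np.exp(-1j * theta)),
        ]
    elif win.name in _COSINE_SERIES and P > 0:
        terms = []
        for j, a in enumerate(_COSINE_SERIES[win.name]):
            if j == 0:
                terms.append(ExpTerm(complex(a), 1.0 + 0j))
            else:
                theta = j * np.pi / P
                terms.append(ExpTerm(a / 2 + 0j, np.exp(1j * theta)))
                terms.append(ExpTerm(a / 2 + 0j, np.exp(-1j * theta)))
    elif win.name in _COSINE_SERIES and P == 0:
        terms = [ExpTerm(complex(sum(_COSINE_SERIES[win.name])), 1.0 + 0j)]
    else:
        raise ValueError(
            f"window {win.name!r} admits no exact exponential decomposition; "
            f"admissible families: {RECURSIVE_FAMILIES}"
        )
    m = win.support
    recon = np.zeros(len(win), dtype=complex)
    for t in terms:
        recon += t.coefficient * t.ratio ** m.astype(float)
    err = np.max(np.abs(recon - win.coefficients))
    if err > tol:
        raise AssertionError(f"decomposition reconstruction error {err:.2e}")
    return terms
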