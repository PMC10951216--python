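"""Closed-form model of an idealized second-order band-pass filter.

A second-order band-pass stage (a low-pass and a high-pass in cascade) has
the analog transfer function

    H(s) = (w0/Q) s / (s^2 + (w0/Q) s + w0^2),      s = j*w,

where ``w0 = 2*pi*f0`` is the angular central frequency of the passband and
``Q = f0 / (f_H - f_L)`` is the quality factor.  From the phase response one
obtains the group delay ``tau_g(w) = -d(phi)/dw`` in closed form; the delay
grows as the central frequency falls, which is what makes narrow-band
filtering of pulse waveforms time-shift the systolic peak.

The closed-form delay and a finite-difference evaluation of ``-d(phi)/dw``
serve as mutual cross-checks; both are exposed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "BandSpec",
    "transfer_function",
    "phase_response",
    "group_delay_analytic",
    "group_delay_numeric",
]


@dataclass(frozen=True)
class BandSpec:
    """A band-pass specification with derived central frequency and Q.

    The central frequency uses the arithmetic-midpoint convention
    ``f0 = (f_L + f_H) / 2``: the study bands 0.1-10, 0.1-5 and 0.1-2 Hz then
    have f0 of about 5, 2.5 and 1 Hz and Q of about 0.5 each.

    Parameters
    ----------
    f_low, f_high : float
        Lower and upper cutoff frequencies in Hz, ``0 < f_low < f_high``.
    """

    f_low: float
    f_high: float
    f0: float = field(init=False)
    delta_f: float = field(init=False)
    q: float = field(init=False)

    def __post_init__(self) -> None:
        # f_low == 0 is allowed for the analytic resonator only (exact
        # Q = 0.5 under the midpoint convention); digital designs reject it
        if not (0.0 <= self.f_low < self.f_high):
            raise ParameterError(
                f"need 0 <= f_low < f_high, got ({self.f_low}, {self.f_high})"
            )
        object.__setattr__(self, "f0", 0.5 * (self.f_low + self.f_high))
        object.__setattr__(self, "delta_f", self.f_high - self.f_low)
        object.__setattr__(self, "q", self.f0 / self.delta_f)

    @property
    def omega0(self) -> float:
        """Angular central frequency in rad/s."""
        return 2.0 * np.pi * self.f0

    @classmethod
    def from_center(cls, f0: float, q: float) -> "BandSpec":
        """Build a band from (f0, Q): ``delta_f = f0/Q`` around the midpoint."""
        if f0 <= 0 or q <= 0:
            raise ParameterError("f0 and Q must be positive")
        half_bw = 0.5 * f0 / q
        if half_bw > f0:
            raise ParameterError(
                f"Q={q} too small for midpoint convention (f_low would be < 0)"
            )
        return cls(f0 - half_bw, f0 + half_bw)


def _check_freq(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ParameterError("frequency must be non-negative")
    return f


def transfer_function(band: BandSpec, f):
    """Complex frequency response H(j*2*pi*f) of the ideal 2nd-order band-pass.

    Unity gain with zero phase at ``f = band.f0``; zero at DC.
    """
    f = _check_freq(f)
    s = 1j * 2.0 * np.pi * f
    w0, q = band.omega0, band.q
    return (w0 / q) * s / (s * s + (w0 / q) * s + w0 * w0)


def phase_response(band: BandSpec, f):
    """Phase of the ideal band-pass in radians, wrapped to (-pi, pi].

    Closed form: ``pi/2 - arctan(2Qw/w0 + r) - arctan(2Qw/w0 - r)`` with
    ``r = sqrt(4Q^2 - 1)``; equal to ``arg H`` of :func:`transfer_function`.
    Requires Q >= 0.5 so that r is real.
    """
    f = _check_freq(f)
    q = band.q
    if q < 0.5:
        raise ParameterError(f"phase closed form requires Q >= 0.5, got Q={q}")
    r = np.sqrt(4.0 * q * q - 1.0)
    x = 2.0 * q * (2.0 * np.pi * f) / band.omega0
    phi = np.pi / 2 - np.arctan(x + r) - np.arctan(x - r)
    # wrap to (-pi, pi]
    phi = np.mod(-phi + np.pi, 2.0 * np.pi)
    return np.pi - phi


def group_delay_analytic(band: BandSpec, f):
    """Group delay in seconds of the ideal 2nd-order band-pass (closed form).

    ``tau_g(w) = (2Q/w0) * [1/(1+(x+r)^2) + 1/(1+(x-r)^2)]`` with
    ``x = 2Qw/w0`` and ``r = sqrt(4Q^2-1)``.  Strictly positive; at w=0 it
    equals ``1/(Q*w0)``.  Q < 0.5 is rejected (r would be imaginary).
    """
    f = _check_freq(f)
    q, w0 = band.q, band.omega0
    if q < 0.5:
        raise ParameterError(f"group delay closed form requires Q >= 0.5, got Q={q}")
    r = np.sqrt(4.0 * q * q - 1.0)
    x = 2.0 * q * (2.0 * np.pi * f) / w0
    return (2.0 * q / w0) * (1.0 / (1.0 + (x + r) ** 2) + 1.0 / (1.0 + (x - r) ** 2))


def group_delay_numeric(phase: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Group delay ``-d(phi)/d(omega)`` by finite differences on a grid.

    The phase samples are unwrapped before differencing; central differences
    are used in the interior and one-sided differences at the edges.

    Parameters
    ----------
    phase : array of radians sampled on ``omega``
    omega : strictly increasing angular-frequency grid in rad/s, >= 3 points
    """
    phase = np.asarray(phase, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if phase.shape != omega.shape or phase.ndim != 1:
        raise ParameterError("phase and omega must be 1-d arrays of equal length")
    if omega.size < 3:
        raise ParameterError("need at least 3 grid points")
    if np.any(np.diff(omega) <= 0):
        raise ParameterError("omega grid must be strictly increasing")
    return -np.gradient(np.unwrap(phase), omega)
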