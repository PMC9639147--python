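"""Incident-field representations and their fluence.

Two pulse kinds are supported: an analytic Gaussian-enveloped sinusoid and a
known-by-points (tabulated, linearly interpolated) field.  ``fluence`` returns
the time integral of the squared field, int eps(t)^2 dt, in atomic units; the
physical constants relating this to energy per area are absorbed into the
cross-section prefactor (see :mod:`tdraman.raman`) so the two conventions
cancel exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .units import ev_to_au, fs_to_au, vm_to_au

__all__ = ["GaussianPulse", "TabulatedPulse"]


def _unit(vec) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    n = np.linalg.norm(v)
    if not n > 0:
        raise ValueError("polarization vector must be nonzero")
    return v / n


@dataclass(frozen=True)
class GaussianPulse:
    """eps(t) = eps0 * exp(-(t-t0)^2 / (2 sigma^2)) * cos(omega (t-t0) + phase) * pol.

    All fields in atomic units.  The carrier phase is zero at the envelope
    centre (cosine convention), so the field peaks at t0; ``phase`` exposes the
    carrier-envelope offset for the phase-insensitivity checks.
    """

    amplitude: float
    sigma: float
    t0: float
    omega: float
    polarization: np.ndarray = (1.0, 0.0, 0.0)
    phase: float = 0.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        object.__setattr__(self, "polarization", _unit(self.polarization))

    @classmethod
    def from_lab_units(cls, amplitude_v_m: float, sigma_fs: float, t0_fs: float,
                       omega_ev: float, polarization=(1.0, 0.0, 0.0),
                       phase: float = 0.0) -> "GaussianPulse":
        return cls(vm_to_au(amplitude_v_m), fs_to_au(sigma_fs), fs_to_au(t0_fs),
                   ev_to_au(omega_ev), polarization, phase)

    def with_polarization(self, pol) -> "GaussianPulse":
        return replace(self, polarization=_unit(pol))

    def scalar(self, t):
        """Signed field magnitude along the polarization axis (vectorized)."""
        t = np.asarray(t, dtype=float)
        tau = t - self.t0
        return self.amplitude * np.exp(-(tau**2) / (2.0 * self.sigma**2)) * np.cos(
            self.omega * tau + self.phase
        )

    def field_at(self, t):
        s = self.scalar(t)
        return np.multiply.outer(s, self.polarization) if np.ndim(s) else s * self.polarization

    def fluence(self) -> float:
        """int eps(t)^2 dt, exactly (Gaussian times cos^2 integrates in closed form)."""
        carrier = math.exp(-(self.sigma * self.omega) ** 2) * math.cos(2.0 * self.phase)
        return 0.5 * self.amplitude**2 * self.sigma * math.sqrt(math.pi) * (1.0 + carrier)


@dataclass(frozen=True)
class TabulatedPulse:
    """Field sampled on a strictly increasing time grid, zero outside it."""

    times: np.ndarray
    values: np.ndarray
    polarization: np.ndarray = (1.0, 0.0, 0.0)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 2:
            raise ValueError("times and values must be matching 1-D arrays (>= 2 nodes)")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing and unique")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-normalizable tabulated pulse (non-finite values)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "polarization", _unit(self.polarization))

    def with_polarization(self, pol) -> "TabulatedPulse":
        return replace(self, polarization=_unit(pol))

    def scalar(self, t):
        return np.interp(np.asarray(t, dtype=float), self.times, self.values,
                         left=0.0, right=0.0)

    def field_at(self, t):
        s = self.scalar(t)
        return np.multiply.outer(s, self.polarization) if np.ndim(s) else s * self.polarization

    def fluence(self) -> float:
        return float(np.trapezoid(self.values**2, self.times))
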