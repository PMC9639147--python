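"""Real-time propagation of the vibronic coefficients under the incident pulse.

The full time-dependent Schroedinger equation is integrated on the truncated
vibronic basis with the two-step explicit ("second-order Euler") stencil

    c(t+dt) = c(t-dt) - 2i dt [H0 + V(t)] c(t),      V(t) = -mu_hat . eps(t)

started with a single classical RK4 step.  Coefficients carry their absolute
phases exp(-i E_J t) — no rotating frame — because the downstream windowed
Fourier transform (:mod:`tdraman.raman`) needs them.  In the weak-field regime
the excited-surface amplitudes coincide with first-order perturbation theory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import leapfrog_loop
from .units import fs_to_au
from .vibronic import VibronicModel

__all__ = ["PropagationGrid", "CoefficientTrajectory", "interaction_element",
           "propagate_first_order"]

#: abort threshold on the closed-system norm drift (signals dt too large)
NORM_DRIFT_LIMIT = 1e-3


@dataclass(frozen=True)
class PropagationGrid:
    """Uniform time grid in atomic units; every ``stride``-th step is stored."""

    dt: float
    n_steps: int
    stride: int = 1

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.n_steps < self.stride:
            raise ValueError("n_steps must cover at least one stored interval")

    @classmethod
    def from_fs(cls, dt_fs: float, duration_fs: float, stride: int = 1
                ) -> "PropagationGrid":
        dt = fs_to_au(dt_fs)
        n = int(round(fs_to_au(duration_fs) / dt))
        n += (-n) % stride  # uniform stored grid covering the full duration
        return cls(dt, n, stride)

    @property
    def n_stored(self) -> int:
        return self.n_steps // self.stride + 1

    @property
    def dt_stored(self) -> float:
        return self.dt * self.stride

    @property
    def duration(self) -> float:
        return self.dt * self.n_steps

    def stored_times(self) -> np.ndarray:
        return np.arange(self.n_stored) * self.dt_stored

    def step_times(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt


@dataclass
class CoefficientTrajectory:
    """Stored complex coefficients c_J(t) on the vibronic basis."""

    times: np.ndarray            # stored times (a.u.)
    coefficients: np.ndarray     # (n_stored, n_states) complex
    grid: PropagationGrid
    metadata: dict = field(default_factory=dict)

    @property
    def populations(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2

    def norm(self) -> np.ndarray:
        return np.sqrt(self.populations.sum(axis=1))


def interaction_element(model: VibronicModel, pulse, t: float) -> np.ndarray:
    """Interaction operator V(t) = -(mu . eps(t)) on the vibronic basis."""
    if model.dipoles is None:
        raise ValueError("model dipoles are not assembled")
    return -np.tensordot(model.dipoles, np.asarray(pulse.field_at(t)), axes=(2, 0))


def _rk4_start(energies, w, pulse, dt, c0):
    """One RK4 step of i dc/dt = [diag(E) - eps(t) W] c from t=0 (startup)."""

    def rhs(t, c):
        return -1j * (energies * c - pulse.scalar(t) * (w @ c))

    k1 = rhs(0.0, c0)
    k2 = rhs(0.5 * dt, c0 + 0.5 * dt * k1)
    k3 = rhs(0.5 * dt, c0 + 0.5 * dt * k2)
    k4 = rhs(dt, c0 + dt * k3)
    return c0 + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def prepare_run(model: VibronicModel, pulse, grid: PropagationGrid,
                initial_index: int | None = None):
    """Shared setup for the closed and stochastic propagators."""
    if model.dipoles is None:
        raise ValueError("model dipoles are not assembled")
    energies = model.energies
    w = np.ascontiguousarray(model.dipoles @ np.asarray(pulse.polarization))
    eps = np.asarray(pulse.scalar(grid.step_times()), dtype=float)
    c0 = np.zeros(model.n_states, dtype=complex)
    c0[model.initial_index if initial_index is None else initial_index] = 1.0
    c1 = _rk4_start(energies, w, pulse, grid.dt, c0)
    return energies, w, eps, c0, c1


def propagate_first_order(model: VibronicModel, pulse, grid: PropagationGrid,
                          initial_index: int | None = None
                          ) -> CoefficientTrajectory:
    """Closed-system propagation; deterministic, norm-conserving.

    Raises if the final norm drifts beyond ``NORM_DRIFT_LIMIT`` (the leapfrog
    stencil is unstable once |E_max dt| approaches 1, so drift flags a time
    step that is too large for the spectral range of the model).
    """
    energies, w, eps, c0, c1 = prepare_run(model, pulse, grid, initial_index)
    out = np.empty((grid.n_stored, model.n_states), dtype=complex)
    out[0] = c0
    leapfrog_loop(energies, w, eps, grid.dt, grid.stride,
                  c0.copy(), c1.copy(), out)
    drift = abs(np.linalg.norm(out[-1]) - 1.0)
    if not drift <= NORM_DRIFT_LIMIT:  # catches NaN from an unstable run too
        raise RuntimeError(
            f"norm drift {drift:.2e} exceeds {NORM_DRIFT_LIMIT}; reduce dt "
            f"(|E_max dt| = {np.max(np.abs(energies)) * grid.dt:.3f})"
        )
    return CoefficientTrajectory(
        times=grid.stored_times(),
        coefficients=out,
        grid=grid,
        metadata={"pulse": repr(pulse), "norm_drift": float(drift)},
    )
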