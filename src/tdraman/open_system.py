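"""Vibrational relaxation: stochastic Schroedinger equation with quantum jumps,
and the Lindblad master-equation oracle used to validate it.

Each decay channel q carries a jump operator L_q = |target><source| at rate
Gamma_q.  A trajectory follows the Markovian quantum-jump unravelling: at each
step the jump probability p_q = Gamma_q |c_source|^2 dt is evaluated; a Monte
Carlo draw either collapses the wave function onto the channel target (then
renormalizes) or applies the no-jump evolution — the deterministic step plus
the non-Hermitian damping exp(-Gamma_q dt / 2) on the source amplitudes,
followed by renormalization.  Averages over trajectories converge to the
Lindblad master equation, which :func:`propagate_lindblad` integrates
deterministically for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from ._kernels import sse_loop
from .propagation import CoefficientTrajectory, PropagationGrid, prepare_run
from .units import fs_to_au
from .vibronic import VibronicModel

__all__ = [
    "DecayChannel", "EnsembleConfig", "DensityMatrixTrajectory",
    "vibrational_channels", "propagate_sse_trajectory", "run_sse_ensemble",
    "ensemble_populations", "propagate_lindblad",
]

_TRACE_TOL = 1e-6
_JUMP_LOG_CAP = 100_000


@dataclass(frozen=True)
class DecayChannel:
    """One nonradiative decay channel |source> -> |target| at rate ``rate`` (a.u.^-1)."""

    source: int
    target: int
    rate: float

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("decay rate must be non-negative")
        if self.source == self.target:
            raise ValueError("decay channel must connect two distinct states")

    def validate(self, model: VibronicModel):
        s, t = model.basis[self.source], model.basis[self.target]
        if s.surface != t.surface:
            raise ValueError("vibrational decay must stay on one electronic surface")


def vibrational_channels(model: VibronicModel, lifetime_fs: float,
                         include_ground: bool = True) -> list:
    """Default channel topology: every vibrationally excited basis state decays
    to the lowest vibronic level of its own surface with the shared rate
    1/lifetime.  ``include_ground=False`` restricts relaxation to the excited
    electronic surface.
    """
    if lifetime_fs <= 0:
        raise ValueError("lifetime must be positive")
    rate = 1.0 / fs_to_au(lifetime_fs)
    lowest = {}
    for surf in ("ground", "excited"):
        idx = [i for i, s in enumerate(model.basis) if s.surface == surf]
        lowest[surf] = min(idx, key=lambda i: model.basis[i].energy)
    channels = []
    for i, s in enumerate(model.basis):
        if s.total_quanta == 0:
            continue
        if s.surface == "ground" and not include_ground:
            continue
        channels.append(DecayChannel(i, lowest[s.surface], rate))
    return channels


@dataclass(frozen=True)
class EnsembleConfig:
    """Trajectory count and reproducible per-trajectory seeding."""

    n_trajectories: int
    master_seed: int

    def __post_init__(self):
        if self.n_trajectories < 1:
            raise ValueError("at least one trajectory is required")

    def trajectory_seeds(self):
        """Independent child seeds derived deterministically from the master."""
        return np.random.SeedSequence(self.master_seed).spawn(self.n_trajectories)


def propagate_sse_trajectory(model: VibronicModel, pulse, grid: PropagationGrid,
                             channels, seed, initial_index: int | None = None):
    """One quantum-jump realization.

    Returns ``(trajectory, jump_log)`` where ``jump_log`` is a list of
    ``(time_au, channel_index)``.  ``seed`` may be an int or a SeedSequence.
    """
    for ch in channels:
        ch.validate(model)
    energies, w, eps, c0, c1 = prepare_run(model, pulse, grid, initial_index)
    src = np.array([ch.source for ch in channels], dtype=np.int64)
    tgt = np.array([ch.target for ch in channels], dtype=np.int64)
    rates = np.array([ch.rate for ch in channels], dtype=float)
    gamma_state = np.zeros(model.n_states)
    for ch in channels:
        gamma_state[ch.source] += ch.rate
    rng = np.random.default_rng(seed)
    uni = rng.random((grid.n_steps + 1, 2))
    out = np.empty((grid.n_stored, model.n_states), dtype=complex)
    out[0] = c0
    jump_steps = np.zeros(_JUMP_LOG_CAP, dtype=np.int64)
    jump_channels = np.zeros(_JUMP_LOG_CAP, dtype=np.int64)
    n_jumps, err = sse_loop(energies, w, eps, grid.dt, grid.stride,
                            c0.copy(), c1.copy(), gamma_state, src, tgt, rates,
                            uni, out, jump_steps, jump_channels)
    if err:
        raise RuntimeError(
            "per-step jump probability exceeded 0.1; reduce dt for these rates"
        )
    n_logged = min(n_jumps, _JUMP_LOG_CAP)
    log = [(jump_steps[i] * grid.dt, int(jump_channels[i])) for i in range(n_logged)]
    traj = CoefficientTrajectory(
        times=grid.stored_times(), coefficients=out, grid=grid,
        metadata={"pulse": repr(pulse), "n_jumps": int(n_jumps)},
    )
    return traj, log


def run_sse_ensemble(model: VibronicModel, pulse, grid: PropagationGrid,
                     channels, config: EnsembleConfig,
                     initial_index: int | None = None):
    """All trajectories of an ensemble; returns (trajectories, jump_logs)."""
    trajs, logs = [], []
    for child in config.trajectory_seeds():
        t, lg = propagate_sse_trajectory(model, pulse, grid, channels, child,
                                         initial_index)
        trajs.append(t)
        logs.append(lg)
    return trajs, logs


def ensemble_populations(trajectories):
    """Mean per-state populations over trajectories with standard errors.

    Returns ``(times, mean, sem)`` with mean/sem of shape (n_stored, n_states).
    """
    if len(trajectories) < 2:
        raise ValueError("need at least two trajectories to average")
    t0 = trajectories[0].times
    for tr in trajectories[1:]:
        if tr.times.shape != t0.shape or not np.allclose(tr.times, t0):
            raise ValueError("trajectories were stored on different time grids")
    pops = np.stack([tr.populations for tr in trajectories])
    mean = pops.mean(axis=0)
    sem = pops.std(axis=0, ddof=1) / np.sqrt(pops.shape[0])
    return t0, mean, sem


@dataclass
class DensityMatrixTrajectory:
    times: np.ndarray
    rho: np.ndarray  # (n_stored, n, n) complex, Hermitian, unit trace
    metadata: dict = field(default_factory=dict)

    @property
    def populations(self) -> np.ndarray:
        return np.real(np.einsum("tii->ti", self.rho))


def propagate_lindblad(model: VibronicModel, pulse, grid: PropagationGrid,
                       channels, initial_index: int | None = None,
                       rtol: float = 1e-9, atol: float = 1e-12
                       ) -> DensityMatrixTrajectory:
    """Deterministic Lindblad master-equation oracle (dense, small bases only).

        d rho/dt = -i[H(t), rho] + sum_q Gamma_q (L rho L+ - {L+L, rho}/2)
    """
    for ch in channels:
        ch.validate(model)
    if model.dipoles is None:
        raise ValueError("model dipoles are not assembled")
    n = model.n_states
    energies = model.energies
    w = model.dipoles @ np.asarray(pulse.polarization)
    gamma_state = np.zeros(n)
    for ch in channels:
        gamma_state[ch.source] += ch.rate

    def rhs(t, y):
        rho = y.reshape(n, n)
        h = np.diag(energies) - pulse.scalar(t) * w
        drho = -1j * (h @ rho - rho @ h)
        # anticommutator part: diagonal damping on rows and columns
        drho -= 0.5 * (gamma_state[:, None] + gamma_state[None, :]) * rho
        for ch in channels:
            drho[ch.target, ch.target] += ch.rate * rho[ch.source, ch.source].real
        return drho.ravel()

    rho0 = np.zeros((n, n), dtype=complex)
    i0 = model.initial_index if initial_index is None else initial_index
    rho0[i0, i0] = 1.0
    times = grid.stored_times()
    sol = solve_ivp(rhs, (times[0], times[-1]), rho0.ravel(), t_eval=times,
                    rtol=rtol, atol=atol, method="DOP853")
    if not sol.success:
        raise RuntimeError(f"Lindblad integration failed: {sol.message}")
    rho = sol.y.T.reshape(-1, n, n)
    traces = np.real(np.einsum("tii->ti", rho).sum(axis=1))
    drift = np.max(np.abs(traces - 1.0))
    if drift > _TRACE_TOL:
        raise RuntimeError(f"Lindblad trace drift {drift:.2e} exceeds {_TRACE_TOL}")
    return DensityMatrixTrajectory(times=times, rho=rho,
                                   metadata={"trace_drift": float(drift)})
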