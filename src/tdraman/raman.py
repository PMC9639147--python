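"""Cumulative time-dependent Raman/fluorescence cross-sections.

From a stored coefficient trajectory, the second-order (scattered-field)
coefficient of a final ground-surface state N at observation time t is the
windowed Fourier transform

    B_N^{lambda}(w_S, t) = int_0^t dt' [sum_J mu_lambda^{NJ} c_J(t')] e^{i E_N t'} e^{i w_S t'}

evaluated by FFT with a Heaviside window Theta(t - t') and zero padding.  Since
the dipole matrix only connects the two surfaces, only excited-surface
intermediate amplitudes contribute.  Collecting B for the three incident
polarizations (eta) and three scattered projections (lambda) gives, per
(N, w_S, t), a 3x3 tensor that transforms like the transition polarizability;
the isotropic orientational average of the detected intensity is a fixed
combination of its three quadratic rotational invariants

    S0 = |Tr B|^2,  S1 = sum |B_le|^2,  S2 = sum B_le B*_el.

For the default geometry (incident linear polarization perpendicular to the
detection direction, unpolarized detection) the exact fourth-rank isotropic
average gives  Pbar = (S0 + 6 S1 + S2) / 30.

The cumulative cross-section per unit scattered frequency and solid angle is

    sigma(w_S; t) = w_I w_S^3 / (pi c^4 F) * sum_N Pbar_N(w_S, t),
    F = int eps(t)^2 dt,

with the prefactor fixed analytically by requiring the quasi-CW limit to
reproduce the Kramers-Heisenberg-Dirac differential cross-section
(w_I w_S^3/c^4) |alpha|^2; :func:`khd_cross_section` provides that
sum-over-states oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import ifft, next_fast_len

from .open_system import EnsembleConfig, propagate_sse_trajectory
from .propagation import CoefficientTrajectory, PropagationGrid, propagate_first_order
from .units import C_AU, cm1_to_au
from .vibronic import VibronicModel

__all__ = [
    "DetectionSetup", "PERPENDICULAR_UNPOLARIZED", "PARALLEL_POLARIZED",
    "PERPENDICULAR_DEPOLARIZED", "SecondOrderTensorMap", "SpectrumSeries",
    "second_order_map", "assemble_tensor_map", "combine_setup",
    "combine_tensor", "cross_section", "khd_cross_section", "peak_integral",
    "average_spectra", "time_resolved_spectrum", "sse_averaged_spectrum",
]

_AXES = np.eye(3)


@dataclass(frozen=True)
class DetectionSetup:
    """Illumination-detection geometry as rotational-invariant weights.

    The orientation-averaged detected intensity is
    ``(k0*S0 + k1*S1 + k2*S2) / 30`` with the invariants defined above; the
    named geometries below carry the exact coefficients of the fourth-rank
    isotropic rotation average.
    """

    name: str
    k0: float
    k1: float
    k2: float

    def combine(self, s0, s1, s2):
        return (self.k0 * s0 + self.k1 * s1 + self.k2 * s2) / 30.0


#: incident linear polarization perpendicular to the detection direction,
#: both scattered polarizations detected (the default geometry)
PERPENDICULAR_UNPOLARIZED = DetectionSetup("perpendicular_unpolarized", 1.0, 6.0, 1.0)
#: detected polarization parallel to the incident one (<|alpha'_xx|^2>)
PARALLEL_POLARIZED = DetectionSetup("parallel_polarized", 2.0, 2.0, 2.0)
#: detected polarization perpendicular to the incident one (<|alpha'_yx|^2>)
PERPENDICULAR_DEPOLARIZED = DetectionSetup("perpendicular_depolarized", -1.0, 4.0, -1.0)

SETUPS = {s.name: s for s in
          (PERPENDICULAR_UNPOLARIZED, PARALLEL_POLARIZED, PERPENDICULAR_DEPOLARIZED)}


@dataclass
class SecondOrderTensorMap:
    """B_N^{lambda eta}(w_S, t_obs) for all final ground-surface states N."""

    b: np.ndarray                 # (3 lambda, 3 eta, nN, n_tobs, n_omega) complex
    omega: np.ndarray             # scattered frequencies (a.u.)
    t_obs: np.ndarray             # observation times (a.u.)
    final_states: np.ndarray      # basis indices of the final states
    final_energies: np.ndarray

    @property
    def populations(self) -> np.ndarray:
        """|c^(2)|^2 per polarization pair (up to the scattered-field amplitude)."""
        return np.abs(self.b) ** 2


@dataclass
class SpectrumSeries:
    """Cumulative cross-section per (w_S, t_obs): per-state and total."""

    omega: np.ndarray             # (n_omega,) scattered frequency, a.u.
    t_obs: np.ndarray             # (n_tobs,) a.u.
    per_state: np.ndarray         # (nN, n_tobs, n_omega)
    final_states: np.ndarray
    final_energies: np.ndarray
    omega_i: float                # incident carrier frequency, a.u.
    metadata: dict = field(default_factory=dict)

    @property
    def total(self) -> np.ndarray:
        return self.per_state.sum(axis=0)

    @property
    def raman_shift_cm1(self) -> np.ndarray:
        from .units import au_to_cm1
        return au_to_cm1(self.omega_i - self.omega)


def _window_indices(omega_window, l_fft, dt_stored):
    domega = 2.0 * np.pi / (l_fft * dt_stored)
    if omega_window is None:
        lo, hi = 0, l_fft // 2
    else:
        lo = max(0, int(np.ceil(omega_window[0] / domega)))
        hi = min(l_fft // 2, int(np.floor(omega_window[1] / domega)))
        if hi <= lo:
            raise ValueError("empty scattered-frequency window")
    return np.arange(lo, hi + 1), domega


def second_order_map(trajectory: CoefficientTrajectory, model: VibronicModel,
                     observation_times, omega_window=None, pad: int = 8
                     ) -> np.ndarray:
    """Scattered-field coefficients for one incident polarization.

    Returns ``(b, omega)`` where ``b`` has shape (3 lambda, nN, n_tobs,
    n_omega).  ``observation_times`` must lie inside the stored trajectory;
    each one re-windows the integrand with Theta(t_obs - t') before the FFT.
    """
    times = trajectory.times
    dt_s = times[1] - times[0]
    c = trajectory.coefficients
    finals = model.ground_indices
    e_n = model.energies[finals]
    t_obs = np.atleast_1d(np.asarray(observation_times, dtype=float))
    j_obs = np.round(t_obs / dt_s).astype(int)
    if np.any(j_obs < 0) or np.any(j_obs > len(times) - 1):
        raise ValueError("observation time outside the stored trajectory")
    l_fft = next_fast_len(pad * len(times))
    sel, _ = _window_indices(omega_window, l_fft, dt_s)
    omega = 2.0 * np.pi * sel / (l_fft * dt_s)
    # g[t, lambda, N] = sum_J mu_lambda^{NJ} c_J(t) * exp(i E_N t)
    dip_fin = model.dipoles[finals]                       # (nN, nstates, 3)
    g = np.einsum("tj,njl->tln", c, dip_fin, optimize=True)
    g *= np.exp(1j * np.outer(times, e_n))[:, None, :]
    b = np.empty((3, len(finals), len(t_obs), len(sel)), dtype=complex)
    for it, j in enumerate(j_obs):
        windowed = np.zeros((len(times), 3, len(finals)), dtype=complex)
        windowed[: j + 1] = g[: j + 1]
        spec = ifft(windowed, n=l_fft, axis=0)[sel] * (l_fft * dt_s)
        b[:, :, it, :] = np.moveaxis(spec, 0, -1)
    return b, omega


def assemble_tensor_map(per_eta, omega, observation_times, model: VibronicModel
                        ) -> SecondOrderTensorMap:
    """Stack per-incident-polarization maps into the full (lambda, eta) tensor.

    ``per_eta`` is a sequence of the three ``second_order_map`` outputs for
    incident polarization along x, y, z (in that order).
    """
    if len(per_eta) != 3:
        raise ValueError("need the three incident polarizations x, y, z")
    finals = model.ground_indices
    b = np.stack(per_eta, axis=1)  # (lambda, eta, nN, nt, nw)
    return SecondOrderTensorMap(
        b=b, omega=np.asarray(omega),
        t_obs=np.atleast_1d(np.asarray(observation_times, dtype=float)),
        final_states=finals, final_energies=model.energies[finals],
    )


def combine_tensor(t3x3: np.ndarray, setup: DetectionSetup = PERPENDICULAR_UNPOLARIZED
                   ) -> float:
    """Orientation-averaged detected intensity for a single 3x3 complex tensor."""
    t3x3 = np.asarray(t3x3)
    s0 = abs(np.trace(t3x3)) ** 2
    s1 = float(np.sum(np.abs(t3x3) ** 2))
    s2 = float(np.real(np.sum(t3x3 * t3x3.T.conj())))
    return float(setup.combine(s0, s1, s2))


def combine_setup(tmap: SecondOrderTensorMap,
                  setup: DetectionSetup = PERPENDICULAR_UNPOLARIZED) -> np.ndarray:
    """Isotropically averaged populations Pbar_N(w_S, t_obs), shape (nN, nt, nw)."""
    b = tmap.b
    if b.shape[0] != 3 or b.shape[1] != 3:
        raise ValueError("tensor map must hold all 3x3 polarization components")
    s0 = np.abs(np.einsum("lln...->n...", b)) ** 2
    s1 = np.sum(np.abs(b) ** 2, axis=(0, 1))
    s2 = np.real(np.einsum("len...,eln...->n...", b, b.conj()))
    return setup.combine(s0, s1, s2)


def cross_section(tmap: SecondOrderTensorMap, pulse, omega_i: float | None = None,
                  setup: DetectionSetup = PERPENDICULAR_UNPOLARIZED,
                  metadata: dict | None = None) -> SpectrumSeries:
    """Cumulative cross-section per unit solid angle and scattered frequency (a.u.)."""
    fl = pulse.fluence()
    if not fl > 0.0:
        raise ValueError("cross-section undefined for zero incident fluence")
    if omega_i is None:
        omega_i = getattr(pulse, "omega", None)
        if omega_i is None:
            raise ValueError("omega_i must be given for pulses without a carrier")
    pbar = combine_setup(tmap, setup)
    pref = omega_i * tmap.omega**3 / (np.pi * C_AU**4 * fl)
    meta = {"setup": setup.name, "fluence": fl}
    meta.update(metadata or {})
    return SpectrumSeries(
        omega=tmap.omega, t_obs=tmap.t_obs, per_state=pbar * pref,
        final_states=tmap.final_states, final_energies=tmap.final_energies,
        omega_i=float(omega_i), metadata=meta,
    )


# ---------------------------------------------------------------------------
# KHD sum-over-states oracle (CW limit)
# ---------------------------------------------------------------------------

@dataclass
class KHDResult:
    """Per-final-state CW Raman lines from the resonant-term KHD polarizability."""

    final_states: np.ndarray
    omega_s: np.ndarray            # line positions w_I - E_N (a.u.)
    alpha: np.ndarray              # (nN, 3, 3) transition polarizabilities
    cross_sections: np.ndarray     # integrated dsigma/dOmega per line (a.u.)


def khd_cross_section(model: VibronicModel, omega_i: float,
                      setup: DetectionSetup = PERPENDICULAR_UNPOLARIZED,
                      damping: float = 0.0) -> KHDResult:
    """Sum-over-states transition polarizability and per-line cross-sections.

    alpha_N^{le}(w_I) = sum_J mu_l^{NJ} mu_e^{J0} / (E_J - E_0 - w_I - i gamma)
    over excited-surface intermediates J; antiresonant term omitted, matching
    the time-dependent route.  Off resonance ``damping`` may be zero; exactly
    on a pole it must be positive.
    """
    if model.dipoles is None:
        raise ValueError("model dipoles are not assembled")
    exc = model.excited_indices
    finals = model.ground_indices
    e0 = model.energies[model.initial_index]
    denom = model.energies[exc] - e0 - omega_i - 1j * damping
    if damping == 0.0 and np.any(np.abs(denom) < 1e-12):
        raise ValueError("incident frequency sits on a pole; provide damping > 0")
    mu_nj = model.dipoles[np.ix_(finals, exc)]       # (nN, nJ, 3)
    mu_j0 = model.dipoles[exc, model.initial_index]  # (nJ, 3)
    alpha = np.einsum("njl,je,j->nle", mu_nj, mu_j0, 1.0 / denom)
    omega_s = omega_i - (model.energies[finals] - e0)
    combined = np.array([combine_tensor(alpha[i], setup) for i in range(len(finals))])
    sig = omega_i * omega_s**3 / C_AU**4 * combined
    sig[omega_s <= 0] = 0.0
    return KHDResult(final_states=finals, omega_s=omega_s, alpha=alpha,
                     cross_sections=sig)


# ---------------------------------------------------------------------------
# Spectrum post-processing
# ---------------------------------------------------------------------------

def peak_integral(series: SpectrumSeries, band_cm1, per_state: bool = False
                  ) -> np.ndarray:
    """Trapezoidal integral of the spectrum over a Raman-shift band, per t_obs.

    ``band_cm1 = (lo, hi)`` selects scattered frequencies with Raman shift
    w_I - w_S inside [lo, hi] cm^-1.
    """
    lo, hi = band_cm1
    if hi <= lo:
        raise ValueError("empty integration band")
    w_hi = series.omega_i - cm1_to_au(lo)
    w_lo = series.omega_i - cm1_to_au(hi)
    mask = (series.omega >= w_lo) & (series.omega <= w_hi)
    if mask.sum() < 2:
        raise ValueError("band contains fewer than two grid points")
    values = series.per_state if per_state else series.total
    return np.trapezoid(values[..., mask], series.omega[mask], axis=-1)


def average_spectra(series_list):
    """Pointwise mean of spectra on identical grids; returns (mean, se_total)."""
    if not series_list:
        raise ValueError("no spectra to average")
    ref = series_list[0]
    for s in series_list[1:]:
        if (s.omega.shape != ref.omega.shape or not np.allclose(s.omega, ref.omega)
                or not np.allclose(s.t_obs, ref.t_obs)):
            raise ValueError("spectra were computed on different grids")
    stack = np.stack([s.per_state for s in series_list])
    mean = replace(ref, per_state=stack.mean(axis=0),
                   metadata={**ref.metadata, "n_averaged": len(series_list)})
    totals = stack.sum(axis=1)
    if len(series_list) > 1:
        se_total = totals.std(axis=0, ddof=1) / np.sqrt(len(series_list))
    else:
        se_total = np.zeros_like(totals[0])
    return mean, se_total


# ---------------------------------------------------------------------------
# Pipelines
# ---------------------------------------------------------------------------

def _default_window(omega_i):
    return (max(omega_i - 0.02, 1e-4), omega_i + 0.01)


def time_resolved_spectrum(model: VibronicModel, pulse, grid: PropagationGrid,
                           observation_times, setup=PERPENDICULAR_UNPOLARIZED,
                           omega_window=None, pad: int = 8,
                           channels=None, seeds=None) -> SpectrumSeries:
    """Full closed-system pipeline: propagate the three incident polarizations
    x, y, z, build the (lambda, eta) tensor map and return the cross-section.

    If ``channels`` is given, each direction is one stochastic trajectory
    (``seeds``: three per-direction seeds) — used per realization by
    :func:`sse_averaged_spectrum`.
    """
    omega_i = getattr(pulse, "omega", None)
    if omega_window is None and omega_i is not None:
        omega_window = _default_window(omega_i)
    per_eta, omega = [], None
    for k in range(3):
        p = pulse.with_polarization(_AXES[k])
        if channels is None:
            traj = propagate_first_order(model, p, grid)
        else:
            traj, _ = propagate_sse_trajectory(model, p, grid, channels, seeds[k])
        b, omega = second_order_map(traj, model, observation_times,
                                    omega_window, pad)
        per_eta.append(b)
    tmap = assemble_tensor_map(per_eta, omega, observation_times, model)
    return cross_section(tmap, pulse, omega_i, setup)


def sse_averaged_spectrum(model: VibronicModel, pulse, grid: PropagationGrid,
                          observation_times, channels, config: EnsembleConfig,
                          setup=PERPENDICULAR_UNPOLARIZED, omega_window=None,
                          pad: int = 8):
    """Trajectory-averaged cross-section with vibrational relaxation.

    Each realization propagates the three incident polarizations with its own
    reproducible random streams; the per-realization cross-sections are then
    averaged.  Returns ``(mean_series, se_total)``.
    """
    spectra = []
    for child in config.trajectory_seeds():
        seeds = child.spawn(3)
        spectra.append(time_resolved_spectrum(
            model, pulse, grid, observation_times, setup=setup,
            omega_window=omega_window, pad=pad, channels=channels, seeds=seeds))
    return average_spectra(spectra)
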