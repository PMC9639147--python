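"""Vibronic basis, energies, and Franck-Condon / Herzberg-Teller transition dipoles.

The molecule is modelled as two Born-Oppenheimer electronic surfaces (ground
and one excited state), each carrying a set of independent (parallel) harmonic
normal modes that may be displaced and frequency-changed between the surfaces.
The vibronic basis is truncated, by default, to the zero-quanta state plus the
one-quantum fundamental of every mode on each surface.

Conventions
-----------
* Normal coordinates Q_k are dimensionless in the *ground-surface* frequency
  (Q = sqrt(omega_g) x with hbar = m = 1), so the dimensionless displacement
  d_k between the two minima gives a Huang-Rhys factor S_k = d_k^2 / 2.
* Transition dipoles exist only between states on different surfaces; the
  electronic transition dipole is expanded to first order in Q_k
  (Herzberg-Teller), mu(Q) = mu0 + sum_k (dmu/dQ_k) Q_k.
* Energies are re-referenced so the global ground vibronic state sits at 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

from .units import cm1_to_au, ev_to_au

__all__ = [
    "NormalMode",
    "ElectronicSurface",
    "VibronicState",
    "TransitionDipoleModel",
    "VibronicModel",
    "SynthesisSpec",
    "build_basis",
    "fc_integral",
    "ht_integral",
    "assemble_dipoles",
    "synthesize_model",
    "demo_model",
]

_MAX_QUANTA = 200  # recursion guard for the overlap tables


@dataclass(frozen=True)
class NormalMode:
    """One harmonic normal mode shared by the two surfaces.

    Frequencies are stored in hartree; ``displacement`` is the dimensionless
    shift of the excited-surface minimum along this mode (ground-frequency
    convention, Huang-Rhys S = d^2/2).
    """

    index: int
    freq_g: float
    freq_e: float
    displacement: float

    def __post_init__(self):
        if not (self.freq_g > 0.0 and self.freq_e > 0.0):
            raise ValueError(f"mode {self.index}: frequencies must be strictly positive")
        if not math.isfinite(self.displacement):
            raise ValueError(f"mode {self.index}: displacement must be finite")

    @classmethod
    def from_cm1(cls, index: int, freq_g_cm1: float, freq_e_cm1: float,
                 displacement: float) -> "NormalMode":
        return cls(index, cm1_to_au(freq_g_cm1), cm1_to_au(freq_e_cm1), displacement)

    @property
    def huang_rhys(self) -> float:
        return 0.5 * self.displacement**2


@dataclass(frozen=True)
class ElectronicSurface:
    label: str  # "ground" | "excited"
    origin: float  # adiabatic electronic energy at the surface minimum (hartree)


@dataclass(frozen=True)
class VibronicState:
    surface: str
    quanta: tuple
    energy: float  # hartree, re-referenced to the global ground vibronic state

    @property
    def total_quanta(self) -> int:
        return sum(self.quanta)


@dataclass
class TransitionDipoleModel:
    """Electronic transition dipole mu0 and its normal-mode derivatives (a.u.)."""

    mu0: np.ndarray
    dmu_dQ: np.ndarray  # shape (n_modes, 3)

    def __post_init__(self):
        self.mu0 = np.asarray(self.mu0, dtype=float)
        self.dmu_dQ = np.atleast_2d(np.asarray(self.dmu_dQ, dtype=float))
        if self.mu0.shape != (3,):
            raise ValueError("mu0 must be a 3-vector")
        if self.dmu_dQ.size and self.dmu_dQ.shape[1] != 3:
            raise ValueError("each dmu/dQ entry must be a 3-vector")
        if not (np.all(np.isfinite(self.mu0)) and np.all(np.isfinite(self.dmu_dQ))):
            raise ValueError("dipole vectors must be finite")
        if not (np.any(self.mu0) or np.any(self.dmu_dQ)):
            raise ValueError("mu0 and all HT derivatives are zero: unusable model")


# ---------------------------------------------------------------------------
# Franck-Condon / Herzberg-Teller integrals (displaced + distorted oscillators)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=512)
def _overlap_table(ratio: float, d: float, n_e_max: int, n_g_max: int):
    """Overlap matrix O[n_e, n_g] = <n_e|n_g> for 1D harmonic oscillators.

    Computed in dimensionless ground-mode coordinates: the ground oscillator
    has unit frequency centred at 0, the excited one frequency ``ratio``
    centred at ``d``.  Exact recursion obtained by integrating by parts and
    inserting the position operator (both relations close on neighbours):

        sqrt(m+1) O[n,m+1] = [(a-b) sqrt(m) O[n,m-1] + 2 sqrt(ab) sqrt(n) O[n-1,m]
                              + sqrt(2a) b D O[n,m]] / (a+b)
        sqrt(n+1) O[n+1,m] = [2 sqrt(ab) sqrt(m) O[n,m-1] + (b-a) sqrt(n) O[n-1,m]
                              - sqrt(2b) a D O[n,m]] / (a+b)

    with a = 1, b = ratio, D = d.
    """
    a, b, D = 1.0, float(ratio), float(d)
    s = a + b
    O = np.zeros((n_e_max + 1, n_g_max + 1))
    O[0, 0] = (4.0 * a * b) ** 0.25 / math.sqrt(s) * math.exp(-a * b * D * D / (2.0 * s))
    sab = math.sqrt(a * b)
    for m in range(n_g_max):  # first row, n_e = 0
        prev = math.sqrt(m) * O[0, m - 1] if m >= 1 else 0.0
        O[0, m + 1] = ((a - b) * prev + math.sqrt(2.0 * a) * b * D * O[0, m]) / (
            s * math.sqrt(m + 1)
        )
    for n in range(n_e_max):
        for m in range(n_g_max + 1):
            t = 2.0 * sab * math.sqrt(m) * O[n, m - 1] if m >= 1 else 0.0
            t += (b - a) * math.sqrt(n) * O[n - 1, m] if n >= 1 else 0.0
            t -= math.sqrt(2.0 * b) * a * D * O[n, m]
            O[n + 1, m] = t / (s * math.sqrt(n + 1))
    return O


def _check_quanta(v_g: int, v_e: int):
    if v_g < 0 or v_e < 0:
        raise ValueError("vibrational quanta must be non-negative")
    if v_g > _MAX_QUANTA or v_e > _MAX_QUANTA:
        raise ValueError(
            f"quanta beyond the supported recursion depth ({_MAX_QUANTA}); "
            "refusing to return a silently inaccurate overlap"
        )


def fc_integral(mode: NormalMode, v_g: int, v_e: int) -> float:
    """Franck-Condon overlap <v_e | v_g> between the two surfaces of one mode."""
    _check_quanta(v_g, v_e)
    table = _overlap_table(mode.freq_e / mode.freq_g, mode.displacement, v_e, v_g)
    return float(table[v_e, v_g])


def ht_integral(mode: NormalMode, v_g: int, v_e: int) -> float:
    """Matrix element <v_e | Q | v_g> of the dimensionless coordinate.

    Q is decomposed on ground-surface ladder operators,
    Q |m> = (sqrt(m)|m-1> + sqrt(m+1)|m+1>)/sqrt(2), and reuses the FC table.
    """
    _check_quanta(v_g, v_e)
    table = _overlap_table(mode.freq_e / mode.freq_g, mode.displacement, v_e, v_g + 1)
    lower = math.sqrt(v_g) * table[v_e, v_g - 1] if v_g >= 1 else 0.0
    return float((lower + math.sqrt(v_g + 1) * table[v_e, v_g + 1]) / math.sqrt(2.0))


# ---------------------------------------------------------------------------
# Basis construction
# ---------------------------------------------------------------------------

def _quanta_vectors(n_modes: int, max_quanta: int):
    """All quanta tuples with total <= max_quanta, ordered by total then index."""
    out = []
    for total in range(max_quanta + 1):
        for combo in itertools.combinations_with_replacement(range(n_modes), total):
            v = [0] * n_modes
            for k in combo:
                v[k] += 1
            out.append(tuple(v))
    # combinations_with_replacement already yields a deterministic order; for
    # total == 1 this is exactly "one state per mode, in mode order".
    return out


def build_basis(modes: Sequence[NormalMode], surface: ElectronicSurface,
                max_quanta: int = 1, energy_reference: float = 0.0):
    """Vibronic states of one surface truncated at ``max_quanta`` total quanta.

    The default truncation (1) gives the zero-quanta state plus one fundamental
    per mode.  Energies include the zero-point term and are shifted by
    ``energy_reference`` (the caller passes the global ground-state energy).
    """
    if max_quanta < 1:
        raise ValueError("max_quanta must be >= 1")
    freqs = np.array(
        [m.freq_g if surface.label == "ground" else m.freq_e for m in modes]
    )
    zpe = 0.5 * freqs.sum() if len(modes) else 0.0
    states = []
    for v in _quanta_vectors(len(modes), max_quanta):
        e = surface.origin + zpe + float(np.dot(freqs, v)) - energy_reference
        states.append(VibronicState(surface.label, v, e))
    return states


@dataclass
class VibronicModel:
    """Two surfaces, their common mode list, the truncated basis and dipoles.

    ``basis`` concatenates ground-surface states first, then excited-surface
    states; ``dipoles[i, j]`` is the 3-vector transition dipole between basis
    states i and j (zero within a surface, symmetric across).
    """

    surfaces: tuple
    modes: tuple
    dipole_model: TransitionDipoleModel
    basis: list = field(default_factory=list)
    dipoles: np.ndarray | None = None
    fc_table: dict = field(default_factory=dict)   # (g_idx, e_idx) -> multimode FC
    ht_table: dict = field(default_factory=dict)   # (g_idx, e_idx, k) -> <e|Q_k|g>

    @classmethod
    def build(cls, gap: float, modes: Sequence[NormalMode],
              dipole_model: TransitionDipoleModel, max_quanta: int = 1,
              fc_table: dict | None = None, ht_table: dict | None = None,
              ) -> "VibronicModel":
        """Assemble the model from an adiabatic electronic gap (hartree)."""
        if gap <= 0:
            raise ValueError("excited-surface origin must lie above the ground one")
        if dipole_model.dmu_dQ.shape[0] not in (0, len(modes)):
            raise ValueError("number of HT derivative vectors must match the modes")
        ground = ElectronicSurface("ground", 0.0)
        excited = ElectronicSurface("excited", gap)
        ref = 0.5 * sum(m.freq_g for m in modes)  # global ground vibronic energy
        model = cls(
            surfaces=(ground, excited),
            modes=tuple(modes),
            dipole_model=dipole_model,
            fc_table=dict(fc_table or {}),
            ht_table=dict(ht_table or {}),
        )
        model.basis = build_basis(modes, ground, max_quanta, ref) + build_basis(
            modes, excited, max_quanta, ref
        )
        model.dipoles = assemble_dipoles(model)
        return model

    # -- views ------------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.basis)

    @property
    def energies(self) -> np.ndarray:
        return np.array([s.energy for s in self.basis])

    @property
    def ground_indices(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.basis) if s.surface == "ground"])

    @property
    def excited_indices(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.basis) if s.surface == "excited"])

    @property
    def initial_index(self) -> int:
        return 0  # global ground vibronic state (energy 0 by construction)

    @property
    def zero_zero_energy(self) -> float:
        """Energy of the 0-0 vibronic transition (lowest excited state)."""
        return float(self.energies[self.excited_indices].min())


def assemble_dipoles(model: VibronicModel) -> np.ndarray:
    """Transition-dipole matrix on the vibronic basis.

    element(e, g) = mu0 * prod_k FC_k  +  sum_k (dmu/dQ_k) * HT_k * prod_{k'!=k} FC_k'

    Entries from ``model.fc_table`` / ``model.ht_table`` (e.g. imported from an
    external Duschinsky-capable vibronic code) override the analytic per-mode
    factors for that state pair.
    """
    basis = model.basis
    n = len(basis)
    mu0 = model.dipole_model.mu0
    dmu = model.dipole_model.dmu_dQ
    if dmu.shape[0] not in (0, len(model.modes)):
        raise ValueError("number of HT derivative vectors must match the modes")
    dip = np.zeros((n, n, 3))
    g_idx = [i for i in range(n) if basis[i].surface == "ground"]
    e_idx = [i for i in range(n) if basis[i].surface == "excited"]
    for gi_local, i in enumerate(g_idx):
        for ei_local, j in enumerate(e_idx):
            vg, ve = basis[i].quanta, basis[j].quanta
            fcs = [fc_integral(m, vg[k], ve[k]) for k, m in enumerate(model.modes)]
            if (gi_local, ei_local) in model.fc_table:
                fc_prod = model.fc_table[(gi_local, ei_local)]
            else:
                fc_prod = math.prod(fcs) if fcs else 1.0
            vec = mu0 * fc_prod
            for k, m in enumerate(model.modes):
                if not dmu.size or not np.any(dmu[k]):
                    continue
                ht = model.ht_table.get(
                    (gi_local, ei_local, k), None
                )
                if ht is None:
                    ht = ht_integral(m, vg[k], ve[k])
                others = math.prod(f for kk, f in enumerate(fcs) if kk != k)
                vec = vec + dmu[k] * (ht * others)
            dip[i, j] = vec
            dip[j, i] = vec  # real dipoles: Hermitian == symmetric
    return dip


# ---------------------------------------------------------------------------
# Synthetic model generation
# ---------------------------------------------------------------------------

@dataclass
class SynthesisSpec:
    """Ranges for the random synthetic-model generator (test fixtures)."""

    n_modes: int = 2
    freq_range_cm1: tuple = (400.0, 1700.0)
    huang_rhys_range: tuple = (0.05, 0.4)
    gap_ev: float = 2.28
    mu0_norm: float = 1.5
    ht_scale: float = 0.05        # magnitude of dmu/dQ relative draws (a.u.)
    freq_change: float = 0.02     # max fractional ground->excited frequency change
    max_quanta: int = 1


def synthesize_model(spec: SynthesisSpec, seed: int) -> VibronicModel:
    """Random but reproducible vibronic model drawn from ``spec`` ranges."""
    if spec.n_modes < 0:
        raise ValueError("n_modes must be non-negative")
    for lo, hi, name in (
        (*spec.freq_range_cm1, "freq_range_cm1"),
        (*spec.huang_rhys_range, "huang_rhys_range"),
    ):
        if hi < lo:
            raise ValueError(f"empty range for {name}")
    rng = np.random.default_rng(seed)
    modes = []
    for k in range(spec.n_modes):
        fg = rng.uniform(*spec.freq_range_cm1)
        fe = fg * (1.0 + rng.uniform(-spec.freq_change, spec.freq_change))
        s = rng.uniform(*spec.huang_rhys_range)
        modes.append(NormalMode.from_cm1(k, fg, fe, math.sqrt(2.0 * s)))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    dmu = rng.normal(scale=spec.ht_scale, size=(spec.n_modes, 3))
    dip = TransitionDipoleModel(spec.mu0_norm * direction, dmu)
    return VibronicModel.build(ev_to_au(spec.gap_ev), modes, dip,
                               max_quanta=spec.max_quanta)


def demo_model(max_quanta: int = 1) -> VibronicModel:
    """Fixed two-mode chromophore used throughout the documentation and tests.

    A reduced-scale porphyrin-like system: strong in-plane electronic
    transition near 2.28 eV, one mid-frequency totally-symmetric-like mode at
    738 cm^-1 and one high-frequency mode at 1400 cm^-1, small frequency
    softening in the excited state, moderate Huang-Rhys factors, and weak
    Herzberg-Teller activity.
    """
    modes = (
        NormalMode.from_cm1(0, 738.0, 732.0, 0.60),
        NormalMode.from_cm1(1, 1400.0, 1386.0, 0.45),
    )
    dip = TransitionDipoleModel(
        mu0=np.array([1.2, 0.8, 0.0]),
        dmu_dQ=np.array([[0.05, -0.03, 0.0], [0.02, 0.05, 0.01]]),
    )
    return VibronicModel.build(ev_to_au(2.2813), modes, dip, max_quanta=max_quanta)
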