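"""Independent numerical oracles shared by the tests.

Everything here deliberately avoids the package's analytic recursions: harmonic
wavefunctions are evaluated explicitly and integrals are done by quadrature /
dense grids, so agreement with the package is a genuine cross-check.
"""

import numpy as np
from scipy.integrate import quad
from scipy.special import eval_hermite, factorial


def ho_wavefunction(n, freq, center):
    """1D harmonic-oscillator eigenfunction (dimensionless coordinates)."""
    norm = (freq / np.pi) ** 0.25 / np.sqrt(2.0**n * factorial(n))

    def psi(x):
        y = np.sqrt(freq) * (x - center)
        return norm * eval_hermite(n, y) * np.exp(-freq * (x - center) ** 2 / 2.0)

    return psi


def overlap_quad(v_g, v_e, ratio, d, operator=None):
    """<v_e| op |v_g> by adaptive quadrature; ground freq 1 at 0, excited
    freq ``ratio`` at ``d`` (the package's dimensionless convention)."""
    pg = ho_wavefunction(v_g, 1.0, 0.0)
    pe = ho_wavefunction(v_e, ratio, d)
    op = operator if operator is not None else (lambda x: 1.0)
    val, _ = quad(lambda x: pe(x) * op(x) * pg(x), -30.0, 30.0, limit=400)
    return val


def dipole_quad_2mode(model, g_state, e_state):
    """Brute-force 2D grid integral of mu(Q) psi_e psi_g for a 2-mode model."""
    assert len(model.modes) == 2
    q = np.linspace(-10.0, 10.0, 1601)
    q1, q2 = np.meshgrid(q, q, indexing="ij")
    m1, m2 = model.modes
    r1, r2 = m1.freq_e / m1.freq_g, m2.freq_e / m2.freq_g
    pg = (ho_wavefunction(g_state.quanta[0], 1.0, 0.0)(q1)
          * ho_wavefunction(g_state.quanta[1], 1.0, 0.0)(q2))
    pe = (ho_wavefunction(e_state.quanta[0], r1, m1.displacement)(q1)
          * ho_wavefunction(e_state.quanta[1], r2, m2.displacement)(q2))
    mu0 = model.dipole_model.mu0
    dmu = model.dipole_model.dmu_dQ
    out = np.empty(3)
    for c in range(3):
        mu_c = mu0[c] + dmu[0, c] * q1 + dmu[1, c] * q2
        out[c] = np.trapezoid(np.trapezoid(pe * mu_c * pg, q, axis=1), q)
    return out
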