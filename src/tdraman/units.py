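"""Unit conversions. Everything internal is Hartree atomic units (hbar = m_e = e = 1)."""

HARTREE_EV = 27.211386245988          # 1 hartree in eV
AU_TIME_FS = 0.02418884326586         # 1 a.u. of time in fs
CM1_PER_HARTREE = 219474.6313632      # 1 hartree in cm^-1
FIELD_AU_V_PER_M = 5.14220675112e11   # 1 a.u. of electric field in V/m
C_AU = 137.035999084                  # speed of light in a.u.


def ev_to_au(e: float) -> float:
    return e / HARTREE_EV


def au_to_ev(e: float) -> float:
    return e * HARTREE_EV


def cm1_to_au(w: float) -> float:
    return w / CM1_PER_HARTREE


def au_to_cm1(w: float) -> float:
    return w * CM1_PER_HARTREE


def fs_to_au(t: float) -> float:
    return t / AU_TIME_FS


def au_to_fs(t: float) -> float:
    return t * AU_TIME_FS


def vm_to_au(f: float) -> float:
    return f / FIELD_AU_V_PER_M
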