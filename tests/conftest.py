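import numpy as np
import pytest
from hypothesis import settings

import tdraman as td
from tdraman.units import ev_to_au
from tdraman.vibronic import NormalMode, TransitionDipoleModel, VibronicModel

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def demo():
    """The fixed two-mode chromophore (738 / 1400 cm^-1, 0-0 at 2.28 eV)."""
    return td.demo_model()


@pytest.fixture(scope="session")
def one_mode_model():
    """Smallest vibronic model: 1 mode, 4 states (g0, g1, e0, e1)."""
    mode = NormalMode.from_cm1(0, 800.0, 790.0, 0.7)
    dip = TransitionDipoleModel(np.array([1.0, 0.3, 0.1]),
                                np.array([[0.05, 0.0, 0.02]]))
    return VibronicModel.build(ev_to_au(1.5), (mode,), dip)


@pytest.fixture(scope="session")
def two_level_model():
    """0-mode model: a bare electronic two-level system with mu = x."""
    dip = TransitionDipoleModel(np.array([1.0, 0.0, 0.0]), np.zeros((0, 3)))
    return VibronicModel.build(0.12, (), dip)
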