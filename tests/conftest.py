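import numpy as np
import pytest

from biosas import synthgen as sg
from biosas.sas_model import ScatteringCurve

SPHERE_R = 3.0
SPHERE_RG = np.sqrt(3.0 / 5.0) * SPHERE_R     # ~2.3238 nm
SPHERE_I0 = 100.0


@pytest.fixture(scope="session")
def q_grid():
    return np.linspace(0.05, 5.0, 1000)


@pytest.fixture(scope="session")
def guinier_curve(q_grid):
    """Noiseless curve of exact Guinier form, Rg = 2 nm, I0 = 100."""
    return ScatteringCurve(q_grid, sg.guinier_intensity(q_grid, 2.0, 100.0))


@pytest.fixture(scope="session")
def sphere_curve(q_grid):
    """Noiseless sphere form-factor curve, R = 3 nm, I0 = 100."""
    return ScatteringCurve(q_grid, sg.sphere_intensity(q_grid, SPHERE_R, SPHERE_I0))


@pytest.fixture(scope="session")
def noisy_sphere_curve(sphere_curve):
    """The default noisy synthetic protein: sphere R = 3 nm at exposure 1e5."""
    return sg.add_noise(sphere_curve, 1e5, seed=1)


@pytest.fixture(scope="session")
def default_sec():
    """The default two-component SEC-SAXS simulation (seed 7, 1000 frames)."""
    partials, truth, info = sg.default_sec_run(seed=7)
    return partials, truth, info


@pytest.fixture(scope="session")
def small_geometry():
    return sg.default_geometry((128, 128))
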