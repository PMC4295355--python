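import numpy as np
import pytest

from tissuediff.signal import CompartmentSet, extended_b_grid, synthesize_on_grid

# Printed control-group means: fast 1.25e-9 m^2/s, slow 1.67e-11 m^2/s, p1 0.48.
CONTROL_MEANS = CompartmentSet(d_fast=1.25e-9, d_slow=1.67e-11, p1=0.48)
# Printed cancer-group means in the same units.
CANCER_MEANS = CompartmentSet(d_fast=0.97e-9, d_slow=0.86e-11, p1=0.75)


@pytest.fixture(scope="session")
def b_grid():
    """Merged extended b grid (four diffusion times, g ramp to 4 T/m)."""
    return extended_b_grid()


@pytest.fixture(scope="session")
def control_compartments():
    return CONTROL_MEANS


@pytest.fixture(scope="session")
def control_curve(b_grid, control_compartments):
    """Noise-free biexponential decay at the control-group mean parameters."""
    return synthesize_on_grid(b_grid, control_compartments, noise_sigma=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
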