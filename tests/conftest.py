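import numpy as np
import pytest
from hypothesis import settings

from miecg.forcefield import default_forcefield

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ff():
    return default_forcefield()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def finite_difference_forces(energy_fn, positions, indices, h=1e-5):
    """Central-difference gradient probe at selected (site, axis) pairs."""
    out = []
    for i, d in indices:
        pp = positions.copy()
        pp[i, d] += h
        pm = positions.copy()
        pm[i, d] -= h
        out.append(-(energy_fn(pp) - energy_fn(pm)) / (2 * h))
    return np.array(out)
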