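import numpy as np
import pytest

from rcpvc import phantom as ph
from rcpvc.calibration import calibrate_from_simulation

BACKGROUND = 0.01258


@pytest.fixture(scope="session")
def calibrated():
    """RC surface + samples calibrated once on the simulated six-sphere phantom."""
    surface, samples = calibrate_from_simulation(seed=1)
    return surface, samples


@pytest.fixture(scope="session")
def noiseless_sphere_volume():
    """A 17 mm sphere at L/B 8, noiseless, with its spec (fast shared fixture)."""
    spec = ph.single_sphere_phantom(17.0, 8 * BACKGROUND, noise_scale=0.0)
    return ph.simulate_phantom(spec), spec


def center_seed_voxel(spec):
    return np.rint(
        np.asarray(spec.lesions[0].center_mm) / np.asarray(spec.voxel_size_mm)
    ).astype(int)
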