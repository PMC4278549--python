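import numpy as np
import pytest

from mcdmri.model_space import get_model
from mcdmri.protocol import AcquisitionScheme, reference_protocol
from mcdmri.synthetic import CC_MODEL, CC_PARAMS, rician_noise

#: number of voxels averaged into one analysis signal (mirrors the 24-voxel
#: corpus-callosum average the study fits)
N_AVERAGE = 24
SIGMA = 0.05


@pytest.fixture(scope="session")
def scheme():
    """The full 32-shell, 1536-row protocol."""
    return reference_protocol(seed=1)


@pytest.fixture(scope="session")
def cc_clean(scheme):
    """Noise-free corpus-callosum-like signal (ZeppelinCylinderDot)."""
    return get_model(CC_MODEL).predict(dict(CC_PARAMS), scheme)


def averaged_voxel(clean, sigma=SIGMA, n_avg=N_AVERAGE, seed=0):
    """Average of independently Rician-corrupted copies of a clean signal."""
    rng = np.random.default_rng(seed)
    return np.array([rician_noise(clean, sigma, rng) for _ in range(n_avg)]).mean(axis=0)


@pytest.fixture(scope="session")
def cc_voxel(cc_clean):
    """One voxel-averaged noisy dataset at the study noise level."""
    return averaged_voxel(cc_clean, seed=7)


def single_row_scheme(G=0.060, delta=22e-3, Delta=90e-3, direction=(1.0, 0.0, 0.0)):
    """A scheme with one weighted row (plus its shell b=0) for closed-form checks."""
    return AcquisitionScheme(
        directions=np.array([[0.0, 0.0, 0.0], list(direction)]),
        G=np.array([0.0, G]),
        delta=np.array([delta, delta]),
        Delta=np.array([Delta, Delta]),
        shell_id=np.array([0, 0]),
    )
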