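import numpy as np
import pytest

from qbtrack.formats import DWIVolume, ImageGrid
from qbtrack.phantom import (DEFAULT_FIBER_EVALS, make_gradient_table,
                             make_preset_phantom, multi_tensor_signal,
                             tensor_from_axis)
from qbtrack.sphere import make_sphere

BVAL = 2000.0
S0 = 1000.0


@pytest.fixture(scope="session")
def gtab():
    """The acquisition-matched scheme: 55 directions at b=2000 plus one b0."""
    return make_gradient_table(seed=0)


@pytest.fixture(scope="session")
def sphere():
    return make_sphere(4)


def voxel_dwi(signal, gtab, shape=(1, 1, 1), voxel_mm=2.2):
    """Tile a single-voxel signal vector into a DWIVolume."""
    data = np.tile(np.asarray(signal, dtype=float), shape + (1,))
    return DWIVolume(data, ImageGrid.isotropic(shape, voxel_mm), gtab)


def tensor_signal(gtab, axes, fractions=None, evals=DEFAULT_FIBER_EVALS,
                  s0=S0):
    """Noise-free multi-tensor signal on the full gradient table (b0 = S0)."""
    axes = np.atleast_2d(axes)
    if fractions is None:
        fractions = np.full(len(axes), 1.0 / len(axes))
    tensors = [tensor_from_axis(a, evals) for a in axes]
    sig = multi_tensor_signal(gtab.bvecs, BVAL, fractions, tensors, S0=s0)
    sig = np.asarray(sig)
    sig[gtab.b0_mask] = s0
    return sig


@pytest.fixture(scope="session")
def straight_phantom():
    return make_preset_phantom("straight-bundle")


@pytest.fixture(scope="session")
def ifof_phantom_snr30():
    return make_preset_phantom("ifof-like", snr=30, seed=7)
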