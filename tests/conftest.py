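import numpy as np
import pytest

from cedsim import (
    PhantomTissueParams,
    RunConfig,
    estimate_water_tensors,
    generate_labels,
    generate_propagators,
    make_default_scheme,
    synthesize_signals,
)
from cedsim.fields import mat_to_vec6
from cedsim.phantom import GaussianMixturePropagatorField
from cedsim.workflows import PhantomData, build_phantom

DELTA = 0.03  # diffusion time used throughout the fixtures, s


def single_voxel_propagators(weights, tensors, delta=DELTA):
    """Wrap per-component (weight, 3x3 diffusivity) pairs as a 1-voxel field."""
    weights = np.asarray(weights, dtype=float)
    k = len(weights)
    t6 = np.stack([mat_to_vec6(np.asarray(t, dtype=float)) for t in tensors])
    return GaussianMixturePropagatorField(
        weights=weights[None, None, None, :],
        tensors=t6[None, None, None, :, :],
        n_components=np.full((1, 1, 1), k, dtype=int),
        delta=delta,
    )


@pytest.fixture(scope="session")
def scheme():
    """Two-shell, 61-direction acquisition (b = 1200/2400 s/mm^2, 1 b0)."""
    return make_default_scheme()


@pytest.fixture(scope="session")
def gaussian_voxel():
    """Single-voxel, single-Gaussian propagator (prolate WM-like tensor)."""
    return single_voxel_propagators([1.0], [np.diag([1.7e-3, 0.3e-3, 0.3e-3])])


@pytest.fixture(scope="session")
def mixture_voxel():
    """Two-component mixture with closed-form second moment diag(1.5,1.5,1)e-3."""
    return single_voxel_propagators(
        [0.5, 0.5], [np.diag([2e-3, 1e-3, 1e-3]), np.diag([1e-3, 2e-3, 1e-3])]
    )


@pytest.fixture(scope="session")
def default_phantom():
    """Default 32^3 phantom, seed 3: labels, propagators, scheme, signals."""
    return build_phantom(RunConfig(seed=3), seed=3)


@pytest.fixture(scope="session")
def default_water(default_phantom):
    """Water tensors and scalar maps estimated from the default phantom."""
    return estimate_water_tensors(default_phantom, "cumulant")
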