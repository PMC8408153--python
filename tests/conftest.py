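import numpy as np
import pytest

from spinemetrics import SpinePhantomSpec, make_spine_phantom
from spinemetrics import spine as sp


def aligned_max_error(detected, truth):
    """Max |detected - truth| after removing the constant arc-length origin
    offset between the fitted axis and the generator curve."""
    detected = np.asarray(detected, dtype=float)
    truth = np.asarray(truth, dtype=float)
    assert detected.shape == truth.shape
    offset = detected.mean() - truth.mean()
    return np.abs(detected - offset - truth).max()


def run_spine_chain(phantom, downsample_factor=1.0, bin_um=None, min_sep_um=54.0):
    """Threshold -> head removal -> axis -> profile -> spacings on a phantom,
    with the retained fraction matched to the phantom's bone content."""
    vol = phantom.volume
    if downsample_factor != 1.0:
        vol = sp.downsample(vol, downsample_factor)
    cloud = sp.threshold_to_cloud(vol, phantom.bone_fraction)
    cloud = sp.remove_head(cloud)
    axis = sp.fit_spine_axis(cloud)
    if bin_um is None:
        bin_um = float(np.mean(vol.voxel_size_um))
    profile = sp.project_profile(cloud, axis, bin_um)
    boundaries = sp.find_spacings(profile, 0.1, min_sep_um)
    return vol, cloud, axis, profile, boundaries


@pytest.fixture(scope="session")
def straight_phantom():
    """5 centra, straight axis, no head, noise-free, native resolution."""
    return make_spine_phantom(
        SpinePhantomSpec(
            n_vertebrae=5, centrum_densities=[1, 2, 3, 4, 5],
            axis_curvature=0.0, noise_sd=0.0, head=False, seed=2,
        )
    )


@pytest.fixture(scope="session")
def curved_phantom():
    """10 centra with lateral bow and a head blob, noise-free."""
    return make_spine_phantom(
        SpinePhantomSpec(n_vertebrae=10, noise_sd=0.0, head=True, seed=5)
    )
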