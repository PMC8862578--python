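"""Shared fixtures: phantoms are expensive enough to build once per session."""

import numpy as np
import pytest

import pediplan as pp


@pytest.fixture(scope="session")
def default_phantom():
    """Untreated default phantom: (ct, labels, truth)."""
    return pp.generate_phantom(pp.PhantomSpec())


@pytest.fixture(scope="session")
def corridor_phantom():
    """Phantom with a planted dense corridor through the left pedicle waist."""
    spec = pp.with_corridor(pp.PhantomSpec(seed=3))
    return pp.generate_phantom(spec), spec


@pytest.fixture(scope="session")
def left_frame(default_phantom):
    _, _, truth = default_phantom
    return pp.frame_from_truth(truth, "left")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def uniform_volume(value=1000.0, shape=(20, 20, 20), spacing=1.0, origin=0.0):
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = spacing
    affine[:3, 3] = origin
    return pp.CtVolume(data=np.full(shape, float(value)), affine=affine)


@pytest.fixture
def coarse_search_settings():
    """Small candidate set, enumerable by the brute-force oracle."""
    return pp.SearchSettings(entry_patch_half_extent=1.0, entry_grid_step=1.0,
                             cone_half_angle=6.0, angular_step=3.0, refine=False)
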