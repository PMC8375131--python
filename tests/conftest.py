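"""Shared fixtures: renders are cached per session because they are the
expensive part of the suite."""

import logging

import numpy as np
import pytest

from spherinv.synthetic import SceneSpec, render_spheroid_image

# the r_limit-clipping warning is expected on every default-geometry run
logging.getLogger("spherinv.invasion").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_scene():
    """Default 1040 px scene (core 150 px, 300 cells out to 410 px)."""
    return render_spheroid_image(SceneSpec(seed=3))


@pytest.fixture(scope="session")
def clean_scene():
    """Noiseless, flat-field scene: segmentation is exact on it."""
    spec = SceneSpec(seed=5, noise_sd=0.0, illumination_gradient_ratio=1.0)
    return spec, render_spheroid_image(spec)


@pytest.fixture(scope="session")
def small_scene_spec():
    """A quarter-size scene for fast pipeline/CLI round trips."""
    return SceneSpec(
        image_width=520, image_height=520, core_center=(260.0, 260.0),
        core_radius_true=80.0, r_outermost_true=200.0,
        n_invading_cells=80, seed=11,
    )


@pytest.fixture
def disk_mask():
    """Rasterized disk of radius 150 at (520, 520) in a 1040 px frame."""
    yy, xx = np.mgrid[0:1040, 0:1040]
    return (xx - 520.0) ** 2 + (yy - 520.0) ** 2 <= 150.0**2
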