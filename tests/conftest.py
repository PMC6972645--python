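"""Shared fixtures: one small synthetic subject reused across the suite.

The test grid (140 x 140 x 112 fine voxels, ~64 x 64 x 102 mm field of
view) is the smallest geometry on which both vitreous-humor spheres
survive the coarse-grid erosion; generator parameters are otherwise the
package defaults.
"""

import numpy as np
import pytest

from navein import PhantomSpec, PVEMap, generate_flash, generate_phantom

TEST_GRID = (140, 140, 112)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(fine_grid_shape=TEST_GRID)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec, seed=1)


@pytest.fixture(scope="session")
def small_flash_clean(small_spec, small_phantom):
    """Noise-free, bloom-free FLASH volume for segmentation geometry tests."""
    from dataclasses import replace

    spec = replace(small_spec, flash_noise_sd=0.0, vein_bloom_mm=0.0)
    return generate_flash(small_phantom, spec, seed=2)


@pytest.fixture(scope="session")
def truth_pvemap(small_phantom) -> PVEMap:
    t = small_phantom.truth_pve
    return PVEMap(vein=t["vein"], gm=t["gm"], wm=t["wm"], csf=t["csf"], sss=t["sss"], vh=t["vh"])


@pytest.fixture(scope="session")
def psf_free_sodium(small_phantom):
    """Coarse sodium image with no PSF, no noise: plain block averaging."""
    from navein import block_downsample

    return block_downsample(small_phantom.conc_volume)
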