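import numpy as np
import pytest

import stereovalid as sv


@pytest.fixture(scope="session")
def thalamus_phantom() -> sv.SegmentationMask:
    """Thalamus-scale superellipsoid rescaled to 7400 mm^3, 1 mm voxels."""
    return sv.make_phantom(sv.PhantomSpec(target_volume=7400.0))


@pytest.fixture(scope="session")
def sphere12() -> sv.SegmentationMask:
    """Sphere of radius 12 mm at 0.5 mm voxels (closed-form volume oracle)."""
    return sv.make_phantom(sv.PhantomSpec(semi_axes=(12.0, 12.0, 12.0), voxel_size=0.5))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260917)
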