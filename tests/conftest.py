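import numpy as np
import pytest

from tfccmorph import (AnatomicalFrame, PipelineConfig, extract_footprint,
                       generate_phantom)
from tfccmorph.phantom_synth import PhantomSpec

# A coarse, fast phantom shared by pipeline/morphometry/CLI tests: same
# anatomy as the default spec but at 0.25 mm spacing (~370k voxels).
FAST_GRID = dict(grid_shape=(76, 94, 52), spacing=(0.25, 0.25, 0.25))


@pytest.fixture(scope="session")
def fast_phantom():
    spec = PhantomSpec(seed=3, **FAST_GRID)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def fast_patch(fast_phantom):
    _, volume, truth = fast_phantom
    cfg = PipelineConfig(seed=3, ransac_iterations=300)
    return extract_footprint(volume, 3, 2, cfg,
                             truth.landmark_positions["fovea"])


@pytest.fixture
def identity_frame():
    return AnatomicalFrame()


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
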