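import numpy as np
import pytest

from focalseg.focusmap import ScanConfig, focus_map_stack
from focalseg.masking import otsu_threshold
from focalseg.synthetic import SyntheticStackSpec, generate_focal_stack, shepp_logan


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom():
    return shepp_logan(256)


@pytest.fixture(scope="session")
def synthetic_stack():
    """Default 20-slice, 256x256 stack with ground-truth masks."""
    return generate_focal_stack(SyntheticStackSpec(seed=1))


@pytest.fixture(scope="session")
def small_stack():
    """Quick 8-slice, 128x128 stack for cheaper tests."""
    return generate_focal_stack(SyntheticStackSpec(height=128, width=128, n_slices=8, seed=3))


@pytest.fixture(scope="session")
def weak_labels(synthetic_stack):
    """Rule-based Std-pipeline masks for the default synthetic stack."""
    stack, _gt = synthetic_stack
    cfg = ScanConfig.for_shape(stack.voxels.shape[1:], metric="stddev")
    maps = focus_map_stack(stack, cfg)
    return [otsu_threshold(m)[1] for m in maps]
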