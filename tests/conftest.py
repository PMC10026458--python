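import numpy as np
import pytest

import t2phantom as tp
from t2phantom.phantom import GroundTruthMaps


@pytest.fixture(scope="session")
def truth_1p5t():
    """Default nine-tube phantom at 1.5 T, 2 mm pixels (50x50)."""
    return tp.rasterize_layout(tp.default_layout(1.5), pixel_size_mm=2.0)


@pytest.fixture(scope="session")
def rois_1p5t(truth_1p5t):
    return tp.locate_tube_rois(truth_1p5t)


@pytest.fixture(scope="session")
def roi_mask(rois_1p5t, truth_1p5t):
    mask = np.zeros(truth_1p5t.shape, dtype=bool)
    for roi in rois_1p5t:
        mask |= roi.mask
    return mask


def make_uniform_truth(t1_ms, t2_ms, shape=(2, 2)):
    """Single-compartment truth map for scalar sequence checks."""
    lab = np.ones(shape, dtype=np.int16)
    return GroundTruthMaps(
        label_map=lab,
        t1_map=np.full(shape, float(t1_ms)),
        t2_map=np.full(shape, float(t2_ms)),
        pixel_size_mm=1.0,
        tube_labels={"X": 1},
        field_strength_t=1.5,
    )


@pytest.fixture
def uniform_truth():
    return make_uniform_truth
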