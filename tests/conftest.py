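import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from fbrquant.roi import ROI_HEIGHT, ROI_WIDTH, RoiImage
from fbrquant.synthetic import (
    LesionModelParams,
    TissueModelParams,
    generate_control_section,
    generate_implanted_section,
)


def make_roi(value=0, region="upper_cortex", channel="NeuN", pixels=None) -> RoiImage:
    if pixels is None:
        pixels = np.full((ROI_HEIGHT, ROI_WIDTH), value, dtype=np.uint8)
    return RoiImage(pixels=pixels, region=region, channel=channel)


@pytest.fixture(scope="session")
def small_params() -> TissueModelParams:
    """Default tissue model at the standard geometry, fixed seed."""
    return TissueModelParams(seed=11)


@pytest.fixture(scope="session")
def control_pair(small_params):
    return generate_control_section(small_params)


@pytest.fixture(scope="session")
def implanted_pair(small_params):
    return generate_implanted_section(small_params, LesionModelParams())
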