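import numpy as np
import pytest

from mechanocyte import synthetic as syn
from mechanocyte.afm_mapping import build_stiffness_map, segment_height_map


@pytest.fixture(scope="session")
def afm_pipeline():
    """Shared end-to-end AFM map: generated curves, fitted map, segmentation.

    Built once per session because fitting every pixel dominates runtime.
    """
    fmap, truth = syn.gen_force_map(seed=1)
    smap = build_stiffness_map(fmap, truth["tip"])
    mask = segment_height_map(smap.setpoint_height_image)
    return fmap, truth, smap, mask


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
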