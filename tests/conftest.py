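import numpy as np
import pytest

from calfdepth.synthetic_data import (
    CalfShapeParams,
    SceneConfig,
    make_template_contour,
    render_scene,
    simulate_growth,
)
from calfdepth.threshold_segmentation import SegmentationParams


@pytest.fixture(scope="session")
def scene_config():
    return SceneConfig()


@pytest.fixture(scope="session")
def template(scene_config):
    return make_template_contour(scene_config)


@pytest.fixture(scope="session")
def seg_params(template):
    return SegmentationParams(template=template)


@pytest.fixture(scope="session")
def clean_scene(scene_config):
    """One defect-free scene with its ground-truth mask."""
    return render_scene(CalfShapeParams(), scene_config, seed=11, frame_id="clean")


@pytest.fixture(scope="session")
def herd():
    """Default 20-calf longitudinal herd."""
    return simulate_growth(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
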