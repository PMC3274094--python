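import numpy as np
import pytest

from eogkit import (
    FrontEndConfig,
    PipelineConfig,
    calibration_scenario,
    generate_recording,
)
from eogkit.pipeline import fit_user_models


@pytest.fixture(scope="session")
def frontend() -> FrontEndConfig:
    return FrontEndConfig()


@pytest.fixture(scope="session")
def pipeline_cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def calibration_recording(frontend):
    """A default-noise calibration session with its ground truth."""
    spec = calibration_scenario(seed=3)
    return generate_recording(spec, frontend)


@pytest.fixture(scope="session")
def user_models(calibration_recording, pipeline_cfg):
    """Calibration model, blink template and trained RBF for one user."""
    record, truth = calibration_recording
    return fit_user_models(record, truth, pipeline_cfg, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
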