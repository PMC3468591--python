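import numpy as np
import pytest

from dielgam import SceneConfig, default_truth, process_survey, sample_survey


@pytest.fixture(scope="session")
def scene():
    """Default two-day scene used by the expensive end-to-end tests."""
    return SceneConfig(seed=2)


@pytest.fixture(scope="session")
def survey(scene):
    targets, samples, truth_table = sample_survey(scene)
    return targets, samples, truth_table


@pytest.fixture(scope="session")
def table(scene, survey):
    targets, samples, _ = survey
    return process_survey(targets, samples, scene)


@pytest.fixture(scope="session")
def truth(scene):
    return default_truth(scene)


@pytest.fixture(scope="session")
def small_scene():
    """One short day; keeps unit tests that need a real survey cheap."""
    return SceneConfig(seed=7, n_days=1, transect_length=1000.0,
                      bathymetry_knots=[(0.0, 20.0), (500.0, 100.0), (1000.0, 20.0)])


@pytest.fixture(scope="session")
def small_survey(small_scene):
    return sample_survey(small_scene)


@pytest.fixture(scope="session")
def small_table(small_scene, small_survey):
    targets, samples, _ = small_survey
    return process_survey(targets, samples, small_scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
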