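import numpy as np
import pytest

from chromodr import (
    build_face_centered_ccd,
    build_grid,
    default_grid_spec,
    default_rules,
    fit_study_models,
    load_fatty_acid_ccd,
)
from chromodr.reference import STUDY_FACTORS


@pytest.fixture(scope="session")
def study_factors():
    return STUDY_FACTORS


@pytest.fixture(scope="session")
def study_data():
    """(design, responses) of the bundled 18-run CCD dataset."""
    return load_fatty_acid_ccd()


@pytest.fixture(scope="session")
def study_design(study_data):
    return study_data[0]


@pytest.fixture(scope="session")
def study_responses(study_data):
    return study_data[1]


@pytest.fixture(scope="session")
def study_models(study_data):
    """The five response-surface models refit with the published structures."""
    return fit_study_models(*study_data)


@pytest.fixture(scope="session")
def study_rules():
    return default_rules()


@pytest.fixture(scope="session")
def study_grid():
    return build_grid(default_grid_spec())


@pytest.fixture(scope="session")
def canonical_design(study_factors):
    return build_face_centered_ccd(study_factors, n_center=4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
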