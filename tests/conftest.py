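import numpy as np
import pytest

from carotexture import SyntheticConfig, feature_table, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """6+6+6 patients, 2 images each — shared across stats/classification tests."""
    cfg = SyntheticConfig(
        n_patients={"PA": 6, "EH": 6, "C": 6}, images_per_patient=2, seed=202
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return feature_table(small_cohort)


@pytest.fixture(scope="session")
def small_clinical(small_cohort):
    return small_cohort.clinical_frame()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
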