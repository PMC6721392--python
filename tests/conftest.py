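import numpy as np
import pytest

from mixstrat import CohortConfig, DiagnosisLabel, default_group_params, generate_cohort


@pytest.fixture(scope="session")
def group_params():
    return default_group_params()


@pytest.fixture(scope="session")
def default_cohort():
    """The default-sized cohort (147 patients + 25 controls) at seed 1."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def study_sized_cohort():
    """Cohort at the biological group sizes without MI, plus controls (seed 1)."""
    sizes = {
        DiagnosisLabel.SIVD: 53,
        DiagnosisLabel.AD: 25,
        DiagnosisLabel.MX: 22,
        DiagnosisLabel.LA: 29,
        DiagnosisLabel.CONTROL: 25,
    }
    return generate_cohort(CohortConfig(group_sizes=sizes, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
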