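import numpy as np
import pytest

from nirsnet import CohortSpec, default_montage, simulate_cohort, simulate_hemoglobin_cohort


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def clean_cohort(montage):
    """Small artifact-free cohort at full duration, for round-trip checks."""
    spec = CohortSpec(n_per_group=2, duration_s=600.0, artifact_rate_per_min=0.0, seed=3)
    return simulate_cohort(spec, montage)


@pytest.fixture(scope="session")
def hemo_cohort(montage):
    """Default-condition hemoglobin-stage cohort (13 + 13 subjects)."""
    return simulate_hemoglobin_cohort(CohortSpec(seed=7), montage)


@pytest.fixture(scope="session")
def hemo_rec(hemo_cohort):
    return hemo_cohort[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
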