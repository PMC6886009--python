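import numpy as np
import pytest

from neuromlm import CohortConfig, PipelineConfig, analyze_cohort
from neuromlm.cohort import ParadigmConfig, simulate_cohort_data


@pytest.fixture(scope="session")
def recovery_cohort():
    """Default study-condition cohort (effect planted at rank 3) plus its
    full two-level analysis; shared across recovery tests."""
    config = CohortConfig(seed=11)
    data = simulate_cohort_data(config)
    result = analyze_cohort(
        data.bolds, data.motions, data.manifest, PipelineConfig(seed=11)
    )
    return data, result


@pytest.fixture(scope="session")
def small_cohort_config():
    """Fast cohort for file-based pipeline tests."""
    return CohortConfig(
        n_per_group=(5, 5),
        sex_counts=((3, 2), (2, 3)),
        grid=(8, 8, 6),
        paradigm=ParadigmConfig(blocks_per_condition=2),
        seed=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
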