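import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

from methylmarker.cohort import (  # noqa: E402
    CohortSpec,
    TissueClass,
    default_model,
    generate_cohort,
)
from methylmarker.reference import CpGCensus, synthetic_promoter  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def promoter():
    """Extended synthetic promoter (census -28..+7)."""
    return synthetic_promoter(include_extension=True)


@pytest.fixture(scope="session")
def census(promoter):
    return CpGCensus.from_region(promoter)


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def small_cohort(model, census):
    spec = CohortSpec(
        class_counts={
            TissueClass.HCC: 8,
            TissueClass.HEPATITIS: 5,
            TissueClass.CIRRHOSIS: 5,
            TissueClass.ADJACENT_NON_HCC: 5,
        },
        n_molecules=150,
        seed=11,
    )
    return generate_cohort(spec, model=model, census=census)
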