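import numpy as np
import pytest

from sstmis.synthetic_data import SyntheticCohortSpec, make_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_spec(**overrides) -> SyntheticCohortSpec:
    """Scaled-down cohort for fast harness tests (4 subjects, m=6)."""
    base = dict(
        n_subjects=4,
        n_classes=3,
        m=6,
        sessions_per_class=3,
        samples_per_session=25,
        seed=77,
    )
    base.update(overrides)
    return SyntheticCohortSpec(**base)


@pytest.fixture(scope="session")
def small_cohort():
    ds, truth = make_cohort(small_spec())
    return ds, truth
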