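import numpy as np
import pytest

from echodsi import CohortSpec, generate_cohort
from echodsi.features import cohort_feature_table


@pytest.fixture(scope="session")
def strong_cohort():
    """The default strong-effect 80-case cohort (40 benign + 40 malignant)."""
    return generate_cohort(CohortSpec(seed=0))


@pytest.fixture(scope="session")
def strong_table(strong_cohort):
    """Nine-feature table + labels + areas for the strong-effect cohort."""
    return cohort_feature_table(strong_cohort)


@pytest.fixture(scope="session")
def mini_cohort():
    """A small cohort for cheap smoke-level checks."""
    spec = CohortSpec(n_benign=3, n_malignant=3, seed=11, depth_mm=24.0, width_mm=15.0)
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
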