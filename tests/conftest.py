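import numpy as np
import pytest

from octafuse.synthetic import CohortSpec, generate_raw_volume, iter_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_raw():
    """One moderate-NPDR high-resolution volume at quarter scale."""
    return generate_raw_volume("hr6", 2, 0.25, np.random.default_rng(42))


@pytest.fixture(scope="session")
def small_raw_uwf():
    return generate_raw_volume("uwf15", 3, 0.25, np.random.default_rng(43))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Fully paired 16-eye cohort at 1/14 scale (fast to generate)."""
    spec = CohortSpec(n_patients=8, p_both_eyes=1.0, p_both_acquisitions=1.0,
                      volume_scale=1 / 14, seed=7)
    return list(iter_cohort(spec))


def random_simplex(rng, n=6):
    p = rng.dirichlet(np.ones(n))
    return p / p.sum()
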