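import numpy as np
import pytest

from wmlseg.synthetic import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_spec():
    """A desk-scale cohort spec that generates in well under a second."""
    return CohortSpec(
        n_subjects=6,
        ail_fraction=0.5,
        severity_mix=(1 / 3, 1 / 3, 1 / 3),
        matrix_size=48,
        slice_count_range=(8, 8),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    subjects, manifest = generate_cohort(tiny_spec)
    return subjects, manifest
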