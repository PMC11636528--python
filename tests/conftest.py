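"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest

from clozanet.models import TrainConfig
from clozanet.syncohort import (CohortConfig, generate_cohort,
                                planted_effects_config)

#: desk-scale overrides used by most fixtures: a smaller grid and shorter
#: scan keep ISC computation and cohort generation fast while preserving the
#: cohort's group structure (38 subjects, 7 positive, 44 references).
SMALL = dict(grid_shape=(8, 8, 8), n_timepoints=80)


@pytest.fixture(scope="session")
def planted_bundle():
    """Cohort with strong planted clinical, VBM and ISC group effects."""
    return generate_cohort(planted_effects_config(seed=11, **SMALL))


@pytest.fixture(scope="session")
def null_bundle():
    """Cohort with no group effects anywhere."""
    return generate_cohort(CohortConfig(seed=12, **SMALL))


@pytest.fixture(scope="session")
def tiny_bundle():
    """Very small cohort for I/O round trips and CLI tests."""
    return generate_cohort(CohortConfig(
        seed=13, n_subjects=10, n_positive=3, n_reference=4,
        n_clinical=12, grid_shape=(4, 4, 4), n_regions=4, n_timepoints=20,
        n_missing_vars=3))


@pytest.fixture
def fast_train():
    """Short training config for tests that only need a trained network."""
    return TrainConfig(iterations=200, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)
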