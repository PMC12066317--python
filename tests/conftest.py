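"""Shared fixtures: synthetic cohorts at the study's default conditions.

Cohorts are session-scoped — generation is deterministic, and no test
mutates them.
"""

import numpy as np
import pytest

from dbsmap import generate_cohort, make_toy_atlas


@pytest.fixture(scope="session")
def atlas():
    return make_toy_atlas()


@pytest.fixture(scope="session")
def small_cohort():
    """Small, fast cohort for I/O and plumbing tests."""
    return generate_cohort(12, "ventral_effect", seed=3, n_fibers_per_bundle=20)


@pytest.fixture(scope="session")
def ventral_cohort():
    """Full-size cohort with a planted ventral-left sweet sphere, low noise."""
    return generate_cohort(56, "ventral_effect", seed=7, noise_sd=0.1)


@pytest.fixture(scope="session")
def tract_cohort():
    """Full-size cohort with planted signed bundle effects."""
    return generate_cohort(56, "tract_only", seed=7)


@pytest.fixture(scope="session")
def null_cohort():
    return generate_cohort(56, "null", seed=11)
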