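"""Shared fixtures: seeded synthetic cohorts reused across test modules.

Cohorts are session-scoped because generation plus the filter grid is the
dominant cost of the suite; every test treats them as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

import ppgdistort as pg
from ppgdistort.synth import NoiseSpec

# Single fixed base seed for the whole suite.
BASE_SEED = 1


@pytest.fixture(scope="session")
def cohort20():
    """Study-sized cohort: 20 records, half class 1, default noise."""
    return pg.generate_cohort(n_records=20, seed=BASE_SEED)


@pytest.fixture(scope="session")
def cohort40():
    """Larger cohort for median-based order-trend checks."""
    return pg.generate_cohort(n_records=40, seed=BASE_SEED)


@pytest.fixture(scope="session")
def quiet_class1_cohort():
    """Noise-free class-1 cohort for parameter-recovery checks."""
    return pg.generate_cohort(
        n_records=10, class1_fraction=1.0, seed=BASE_SEED, noise=NoiseSpec.silent()
    )


@pytest.fixture(scope="session")
def clean_record():
    """One noise-free class-1 record with ground truth."""
    return pg.generate_record(seed=BASE_SEED, noise=NoiseSpec.silent(), morphology_class=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(BASE_SEED)
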