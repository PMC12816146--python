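"""Shared fixtures: small seeded cohorts and light model hyperparameters.

Heavy, full-scale artifacts live in session-scoped fixtures inside
``test_acceptance.py``; everything here is sized for fast unit runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from underserved.cohort import CohortConfig, default_config, generate_cohort
from underserved.ensemble import EnsembleHyperparams


@pytest.fixture(scope="session")
def light_hp() -> EnsembleHyperparams:
    """Reduced boosting budget for unit tests."""
    return EnsembleHyperparams(n_rounds=40, max_depth=3, calibration_folds=3)


@pytest.fixture(scope="session")
def small_cohort():
    """n=4000 default-config cohort; shared, treat as read-only."""
    return generate_cohort(default_config(n=4000, seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """n=4000 cohort with no injected missingness."""
    cfg = CohortConfig(n_dentists=4000, seed=17, missingness_rates={})
    return generate_cohort(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
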