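"""Shared fixtures: small synthetic datasets and reusable fits.

The expensive hierarchical fits are session-scoped so several tests can
inspect the same posterior; everything is generated programmatically
from fixed seeds.
"""

import numpy as np
import pytest

from prioddm.design import (
    DesignConfig,
    generate_design,
    recovery_truth,
    simulate_dataset,
)
from prioddm.hfit import ChainConfig, fit_model
from prioddm.models import build_spec


@pytest.fixture(scope="session")
def model7_truth():
    return recovery_truth()


@pytest.fixture(scope="session")
def recovery_data(model7_truth):
    """10 subjects x 408 trials simulated from the canonical truth."""
    cfg = DesignConfig(n_subjects=10, n_sessions=1, trials_per_session=408, seed=42)
    design = generate_design(cfg)
    rng = np.random.default_rng(42)
    return simulate_dataset(design, model7_truth, rng)


@pytest.fixture(scope="session")
def recovery_fit(recovery_data, model7_truth):
    """Reduced-protocol hierarchical fit of the winning model to its own data."""
    chains = ChainConfig(n_chains=3, n_iter=1500, burn_in=500, seed=42)
    return fit_model(recovery_data, model7_truth.spec, chains)


@pytest.fixture(scope="session")
def small_data():
    """Tiny dataset (3 subjects, 120 trials each) for fast structural tests."""
    truth = recovery_truth()
    cfg = DesignConfig(n_subjects=3, n_sessions=1, trials_per_session=120, seed=7)
    design = generate_design(cfg)
    rng = np.random.default_rng(7)
    return simulate_dataset(design, truth, rng)


@pytest.fixture(scope="session")
def small_fit(small_data):
    """Fast low-dimensional fit (model 4) used by summary/PPC tests."""
    chains = ChainConfig(n_chains=2, n_iter=400, burn_in=150, seed=3)
    return fit_model(small_data, build_spec(4), chains)
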