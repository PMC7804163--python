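import logging

import numpy as np
import pytest

from drspipe import synth
from drspipe.preprocess import SpectraDataset

logging.getLogger("drspipe").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def separable_dataset():
    """Strongly separated two-class dataset (coarse grid, fast)."""
    normal, tumor = synth.default_class_specs(
        contrast=1.0, n_patients=10, sites_per_patient=10)
    ds, _ = synth.generate_dataset(normal, tumor, 630, noise_sd=0.02, seed=7,
                                   grid_step=8.0, return_bundles=False)
    return ds


@pytest.fixture(scope="session")
def noiseless_bundle_pair():
    """One noiseless, jitter-free bundle per class at 1 nm resolution."""
    normal, tumor = synth.default_class_specs(
        contrast=1.0, n_patients=1, sites_per_patient=1,
        per_site_jitter_sd=0.0, per_patient_sd=0.0)
    ds, bundles = synth.generate_dataset(normal, tumor, 630, noise_sd=0.0,
                                         seed=1, grid_step=1.0)
    return normal, tumor, ds, bundles


@pytest.fixture
def toy_dataset():
    """Deterministic 12-sample, 3-feature dataset for split-level checks."""
    rng = np.random.default_rng(99)
    X = rng.normal(size=(12, 3))
    X[:6] += 1.5
    y = np.array([1] * 6 + [-1] * 6)
    return SpectraDataset(X, y, np.array([500.0, 600.0, 700.0]), sdd_um=630.0)
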