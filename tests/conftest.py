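"""Shared fixtures: small synthetic datasets and pipeline parameter sets.

Everything is generated at test time from fixed seeds; heavyweight fixtures
are session-scoped so several tests can share one simulation/preprocessing
run.
"""

import logging
import warnings

import numpy as np
import pytest

from gcimstools.preprocess import PreprocessParams, PsalsaParams, SGParams
from gcimstools.synthetic import SynthConfig, simulate_dataset

logging.getLogger("gcimstools").setLevel(logging.ERROR)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def synth_preprocess_params(**overrides) -> PreprocessParams:
    """Pipeline parameters matched to the simulator's intensity scale.

    Psalsa lambdas differ per axis on purpose: the drift-axis baseline is a
    fast exponential (flexible fit), while the retention-axis baseline must
    stay stiff so RIP-depletion dips survive as negative excursions.
    """
    kw = dict(
        sg_drift=SGParams(5, 2),
        sg_retention=SGParams(9, 2),
        psalsa_drift=PsalsaParams(1e5, 5e-3, 50.0),
        psalsa_retention=PsalsaParams(1e8, 5e-3, 50.0),
        rip_retention_window=(0.0, 20.0),
        tic_drift_window=(7.2, 15.0),
        cow_overlap=5,
    )
    kw.update(overrides)
    return PreprocessParams(**kw)


@pytest.fixture(scope="session")
def small_dataset():
    """6-sample clean dataset on a small grid, with ground truth."""
    cfg = SynthConfig(n_per_class=(3, 3), n_retention=300, n_drift=120,
                      peak_catalog_size=12, marker_count=4,
                      noise_sd=5.0, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    return small_dataset[0][0]


@pytest.fixture(scope="session")
def two_class_features():
    """Plain numeric two-class feature matrix for modeling tests."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(40, 30))
    y = np.array([0] * 20 + [1] * 20)
    X[y == 1, :5] += 1.5
    return X, y
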