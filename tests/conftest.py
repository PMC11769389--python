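import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import soilnose as sn

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")

SEED = 20250380

#: Small SVM/RF grids keep unit-test grid searches fast; acceptance tests
#: use the package defaults.
SMALL_SVM = {"C": [1.0, 10.0], "gamma": [0.01, 0.1]}
SMALL_RF = {"n_estimators": [50], "max_depth": [None]}


def small_svm_spec(seed=SEED):
    return sn.ClassifierSpec("SVM", grid=dict(SMALL_SVM), seed=seed)


def small_rf_spec(seed=SEED):
    return sn.ClassifierSpec("RF", grid=dict(SMALL_RF), seed=seed)


def make_config(counts=None, duration_s=10.0, seed=SEED, noise_sd=0.02, **kw):
    cfg = sn.default_study_config(seed=seed, noise_sd=noise_sd)
    if counts is not None:
        counts = {**{c: 0 for c in cfg.counts}, **counts}
        cfg = dataclasses.replace(cfg, counts=counts)
    return dataclasses.replace(cfg, duration_s=duration_s, **kw)


@pytest.fixture(scope="session")
def small_config():
    # 1000 time points keep the default level-7 wavelet feasible.
    counts = {
        "healthy": 20,
        "gasoline": 12,
        "diesel": 12,
        **{p: 12 for p in sn.PESTICIDE_CLASSES},
    }
    return make_config(counts=counts, duration_s=10.0)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return sn.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def flat_profile():
    """Noise-free, drift-free constant-baseline profile for closed-form checks."""
    return sn.SensorProfile(
        class_id="healthy",
        amplitude=np.zeros(sn.N_CHANNELS),
        rise_time_s=5.0,
        baseline=np.full(sn.N_CHANNELS, 0.2),
        drift_slope=np.zeros(sn.N_CHANNELS),
        noise_sd=0.0,
    )


def kinetic_profile(baseline=0.1, amplitude=1.0, rise_time_s=5.0, noise_sd=0.0):
    return sn.SensorProfile(
        class_id="gasoline",
        amplitude=np.full(sn.N_CHANNELS, amplitude),
        rise_time_s=rise_time_s,
        baseline=np.full(sn.N_CHANNELS, baseline),
        drift_slope=np.zeros(sn.N_CHANNELS),
        noise_sd=noise_sd,
    )
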