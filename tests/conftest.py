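import dataclasses

import numpy as np
import pytest

import lipidflux as lf

#: Chase-time grid of the pulse-chase experiment (minutes after loading).
CHASE_TIMES = (4.0, 10.0, 20.0, 30.0, 60.0, 120.0)


@pytest.fixture(scope="session")
def truth_params() -> lf.KineticParams:
    """Generating rates: fast non-vesicular PM->ER, slow vesicular entry."""
    return lf.KineticParams(
        k_pm_endo=0.008, k_endo_golgi=0.05, k_golgi_er=0.05,
        k_pm_er=0.03, k_er_pm=0.02,
    )


@pytest.fixture(scope="session")
def noiseless_config() -> lf.SceneConfig:
    return dataclasses.replace(
        lf.SceneConfig(), poisson_scale=0.0, gaussian_sd=0.0, seed=11
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_config, truth_params) -> lf.SyntheticDataset:
    """Two noise-free fields per chase time from the default geometry."""
    return lf.generate_dataset(
        noiseless_config, truth_params, CHASE_TIMES, n_fields_per_time=2
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
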