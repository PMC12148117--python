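import numpy as np
import pytest

from wl2reg import RegressionData, fit_gamma, fit_wl2, generate_dataset

TRUE_BETA = (0.5, 0.5, 0.5)
TRUE_THETA = 2.0


@pytest.fixture(scope="session")
def sim_data_large():
    """One big dataset from the study's generating process."""
    return generate_dataset(5000, TRUE_BETA, TRUE_THETA, seed=42)


@pytest.fixture(scope="session")
def sim_data_medium():
    return generate_dataset(1000, TRUE_BETA, TRUE_THETA, seed=7)


@pytest.fixture(scope="session")
def wl2_fit_medium(sim_data_medium):
    return fit_wl2(sim_data_medium)


@pytest.fixture(scope="session")
def gamma_fit_medium(sim_data_medium):
    return fit_gamma(sim_data_medium)


@pytest.fixture()
def toy_data():
    rng = np.random.default_rng(3)
    x = rng.uniform(size=40)
    y = rng.gamma(2.0, scale=np.exp(0.2 + 0.5 * x) / 2.0)
    return RegressionData(y=y, X=np.column_stack([np.ones(40), x]))
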