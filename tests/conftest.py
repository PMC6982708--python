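import numpy as np
import pandas as pd
import pytest

import aqproxy as aq


@pytest.fixture(scope="session")
def small_generator_config():
    """Half a year, four predictors: fast but exercises every stage."""
    return aq.GeneratorConfig(
        end="2017-06-30",
        predictors=("acc_mode", "nox", "traffic", "ldsa"),
        seed=0,
    )


@pytest.fixture(scope="session")
def small_tables(small_generator_config):
    return aq.generate(small_generator_config)


@pytest.fixture(scope="session")
def small_proxy_config(small_generator_config):
    return aq.ProxyConfig(
        specs=small_generator_config.variable_specs(),
        thresholds=aq.Thresholds(seed=0),
    )


@pytest.fixture(scope="session")
def small_train_result(small_tables, small_proxy_config):
    table, _ = small_tables
    return aq.train(table, small_proxy_config)


@pytest.fixture
def hourly_index():
    def make(n, start="2017-01-01"):
        return pd.date_range(start, periods=n, freq="1h")

    return make


@pytest.fixture
def linear_data():
    """Exactly linear, noise-free 2-predictor data (zero residuals)."""
    rng = np.random.default_rng(42)
    X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["a", "b"])
    y = pd.Series(1.5 + 2.0 * X["a"] - 0.7 * X["b"])
    return X, y
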