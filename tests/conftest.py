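import numpy as np
import pandas as pd
import pytest

from reefbleach import model as mdl
from reefbleach.synthetic import SimulationConfig, generate_surveys
from reefbleach.thermal import SstSeries


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_islands=2, zones_per_island=2, clusters_per_zone=4)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    surveys, truth = generate_surveys(small_config)
    return surveys, truth


def constant_series(value: float, n_days: int = 6 * 365, island: str = "isl") -> SstSeries:
    dates = pd.date_range("2014-01-01", periods=n_days, freq="D")
    return SstSeries(island_id=island, dates=dates, sst=np.full(n_days, value))


def exact_model(true_beta: "dict[str, float]", data: pd.DataFrame) -> mdl.FittedModel:
    """Fit a model whose coefficients equal ``true_beta`` to machine precision.

    The response is constructed as the exact linear combination of the design,
    so WLS on the true term set returns the prescribed coefficients.
    """
    terms = list(true_beta)
    X = mdl.build_design(data, terms)
    beta = np.array([true_beta[t] for t in terms])
    df = data.copy()
    df["sqrt_pct_bleached"] = X.to_numpy() @ beta
    if "weight" not in df.columns:
        df["weight"] = 1.0
    return mdl.fit_terms(df, terms, "sqrt_pct_bleached")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
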