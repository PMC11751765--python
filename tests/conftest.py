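import numpy as np
import pytest

from smvpd import RunConfig, SyntheticConfig, anomaly_grid, coupling_grid, generate_dataset


@pytest.fixture(scope="session")
def small_run():
    """A 6x6, 8-year default-scenario run shared across tests: generated
    data, anomalies and the monthly coupling table."""
    cfg = RunConfig(seed=7)
    cfg.synthetic = SyntheticConfig(n_lat=6, n_lon=6, n_years=8, seed=7)
    data = generate_dataset(cfg.synthetic)
    anom = anomaly_grid(data.daily, cfg)
    coupling = coupling_grid(anom, data.daily, cfg)
    return cfg, data, anom, coupling


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
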