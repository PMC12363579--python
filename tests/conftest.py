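import dataclasses

import numpy as np
import pytest

from fxtrend import build_series, default_config, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One calibrated default cohort (seed 0), shared across tests."""
    config = default_config(seed=0)
    records, truth = simulate_cohort(config)
    return config, records, truth


@pytest.fixture(scope="session")
def default_series(default_cohort):
    _, records, _ = default_cohort
    return build_series(records)


def gtv_only_config(seed: int, **kwargs):
    """Default calibration restricted to the GTV volume (fast simulation)."""
    cfg = default_config(seed=seed, **kwargs)
    return dataclasses.replace(cfg, specs={"GTV": cfg.specs["GTV"]})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
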