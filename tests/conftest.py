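import numpy as np
import pytest

import riskseg as rs


@pytest.fixture(scope="session")
def default_config():
    return rs.default_truth(n_patients=3000)


@pytest.fixture(scope="session")
def wave1_small(default_config):
    """One seeded wave-1 draw at n=3000 shared across read-only tests."""
    enc, risk, panel, truth = rs.generate_wave1(default_config, seed=42)
    return default_config, enc, risk, panel, truth


@pytest.fixture(scope="session")
def wave1_large():
    """Large boundary-free draw for calibration checks (3-SE tolerances)."""
    cfg = rs.default_truth(n_patients=50_000, boundary_fraction=0.0)
    enc, risk, panel, truth = rs.generate_wave1(cfg, seed=7)
    return cfg, enc, risk, panel, truth


@pytest.fixture(scope="session")
def true_params(default_config):
    return rs.LCAParams(pi=default_config.mixing, rho=default_config.item_probs)
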