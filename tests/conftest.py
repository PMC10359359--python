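import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import dosekit as dk
from dosekit.registry import SCAN_COLUMNS

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def age_table():
    """Published region × age-group coefficient table."""
    return dk.load_age_coefficients()


@pytest.fixture(scope="session")
def diameter_table():
    """Published region × diameter-bin coefficient table."""
    return dk.load_diameter_coefficients()


def make_scans(**overrides) -> pd.DataFrame:
    """Small canonical scan table; columns overridable per test."""
    n = len(next(iter(overrides.values()))) if overrides else 6
    base = {
        "scan_id": [f"s{i}" for i in range(n)],
        "body_region": ["chest"] * n,
        "age": np.linspace(0.5, 20.0, n),
        "sex": ["F"] * n,
        "mean_effective_diameter": np.linspace(12.0, 38.0, n),
        "dlp": np.linspace(80.0, 400.0, n),
        "ctdi_vol": [5.0] * n,
        "scan_length": [25.0] * n,
        "kvp": [120.0] * n,
        "mas": [100.0] * n,
        "manufacturer": ["GE"] * n,
        "reporting_phantom": ["32cm"] * n,
        "is_perfusion": [False] * n,
        "e_reference": [1.0] * n,
    }
    base.update(overrides)
    df = pd.DataFrame(base)
    return df[[c for c in SCAN_COLUMNS]]


@pytest.fixture
def scans_factory():
    return make_scans


@pytest.fixture(scope="session")
def default_noise_registry():
    """Mid-sized synthetic registry at the default noise level (seeded)."""
    cfg = dk.default_config(n_scans=30_000, seed=202)
    return cfg, dk.generate_registry(cfg)
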