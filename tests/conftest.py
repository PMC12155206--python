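import numpy as np
import pandas as pd
import pytest

from neuropls.synthetic import GeneratorConfig, generate_cohort


def standardize(a: np.ndarray) -> np.ndarray:
    return (a - a.mean(axis=0)) / a.std(axis=0, ddof=1)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest multi-site cohort shared by read-only tests."""
    cfg = GeneratorConfig(n_participants=120, n_sites=3, seed=1234,
                          features_per_modality={"FC": 45, "WM": 30, "GM": 40},
                          signal_strength=0.15)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_cohort_frame(**overrides) -> pd.DataFrame:
    """Tiny hand-rolled participant table for filter boundary tests."""
    base = {
        "participant_id": ["P1", "P2", "P3"],
        "site": ["a", "a", "b"],
        "age": [65.0, 70.0, 75.0],
        "sex": [1, 0, 1],
        "education": [12.0, 16.0, 14.0],
        "madrs_baseline": [20.0, 25.0, 15.0],
        "madrs_change": [-5.0, -12.0, -2.0],
        "remission": [0, 1, 0],
        "athf": [8.0, 6.0, 10.0],
        "cirs_g": [7.0, 9.0, 11.0],
        "mean_fd": [0.30, 0.70, 0.69],
        "icv": [1.4e6, 1.5e6, 1.6e6],
        "wmh_volume": [1000.0, 2000.0, 500.0],
        "centile": [0.4, 0.6, 0.5],
        "surface_holes": [100, 380, 381],
    }
    base.update(overrides)
    return pd.DataFrame(base)
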