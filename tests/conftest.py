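import numpy as np
import pandas as pd
import pytest

from scaakit.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_patients=2, glands_per_region=3, peak_count=120, seed=11)
    samples, truth = simulate_cohort(cfg)
    return cfg, samples, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def gland_frame():
    """Minimal hand-built sample table for stages that only need labels."""
    rows = []
    for i, p in enumerate([0.5, 0.6, 0.7, 0.8]):
        rows.append(
            {"sample": f"T{i}", "patient": "P01", "region": "A", "is_normal": False,
             "purity": p}
        )
    for i in range(3):
        rows.append(
            {"sample": f"N{i}", "patient": "P01", "region": "E", "is_normal": True,
             "purity": 0.0}
        )
    return pd.DataFrame(rows)
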