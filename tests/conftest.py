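import numpy as np
import pandas as pd
import pytest

from cropcast.features import WeatherVariable
from cropcast.interface.config import ControlFile
from cropcast.synthetic import make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_panel(values):
    """Build a long weather panel from {(district, year, month): {var: value}}."""
    rows = []
    for (d, y, m), vals in values.items():
        rows.append({"district": d, "year": y, "month": m, **vals})
    return pd.DataFrame(rows)


@pytest.fixture
def two_var_control():
    return ControlFile(
        crop="syn",
        cutoff_month=6,
        variables=[{"id": "tas", "op": "mean"}, {"id": "pr", "op": "sum"}],
        window_min=2,
        window_max=3,
        min_years=15,
        k_retain=10,
        d_max=3,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """12 districts x 20 years, planted 3-feature signal, moderate noise."""
    return make_dataset(n_districts=12, n_years=20, seed=7, noise_share=0.3)


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    from cropcast.interface.pipeline import run_pipeline

    ds = small_dataset
    ctrl = ControlFile(
        crop="syn",
        cutoff_month=6,
        variables=[{"id": "tas", "op": "mean"}, {"id": "pr", "op": "sum"}],
        window_min=2,
        window_max=3,
        min_years=15,
        k_retain=10,
        d_max=3,
    )
    years = list(ds.yields.columns)[3:9]
    return run_pipeline(ds.weather, ds.yields, ds.areas, ds.region_map, ctrl,
                        target_years=years)
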