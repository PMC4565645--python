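import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from urbansami.io import INDICATORS, CensusPanel
from urbansami.synthetic import default_config, generate_panel

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# the reference dynamics include one lag-slope slightly above 1 (a real
# feature of the system being emulated), which the config constructor
# dutifully warns about on every instantiation
warnings.filterwarnings("ignore", message="dynamics spectral radius")


@pytest.fixture(scope="session")
def small_config():
    return default_config(seed=42, n_cities=250)


@pytest.fixture(scope="session")
def small_system(small_config):
    """(panel, truth residual table, coordinates) for a 250-city scenario."""
    return generate_panel(small_config)


@pytest.fixture(scope="session")
def small_panel(small_system):
    return small_system[0]


@pytest.fixture(scope="session")
def truth_table(small_system):
    return small_system[1]


def make_exact_panel(intercept=2.0, exponent=1.5, populations=(100, 1000, 10_000, 100_000),
                     year=2000, indicator="homicides"):
    """Panel whose single indicator lies exactly on a given allometric line."""
    pops = np.asarray(populations, dtype=float)
    frame = pd.DataFrame({
        "city_id": [f"{i:03d}" for i in range(len(pops))],
        "city_name": "x",
        "state": "ZZ",
        "year": year,
        "population": pops,
        indicator: 10.0 ** (intercept + exponent * np.log10(pops)),
    })
    return CensusPanel(frame, (indicator,))


@pytest.fixture
def exact_panel():
    return make_exact_panel()


@pytest.fixture
def toy_panel_csv(tmp_path):
    """Well-formed 3-city, 2-year panel CSV with all eight indicators."""
    rows = []
    rng = np.random.default_rng(0)
    for year in (1991, 2000):
        for i in range(3):
            row = {
                "city_id": f"{i + 1:07d}", "city_name": f"c{i}", "state": "AA",
                "year": year, "population": 10_000 * (i + 1),
            }
            for ind in INDICATORS:
                row[ind] = float(rng.uniform(10, 1000))
            rows.append(row)
    path = tmp_path / "panel.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
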