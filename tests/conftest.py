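import numpy as np
import pandas as pd
import pytest

from foodnet.panel import BipartitePanel


@pytest.fixture
def rng():
    return np.random.default_rng(20110101)


@pytest.fixture
def small_panel():
    """3 countries x 3 products with a nested support pattern."""
    W = np.array(
        [
            [2.0, 1.0, 0.5],
            [1.0, 0.25, 0.0],
            [0.5, 0.0, 0.0],
        ]
    )
    return BipartitePanel.from_weighted(2011, ["A", "B", "C"], ["p1", "p2", "p3"], W)


@pytest.fixture
def production_csv(tmp_path):
    path = tmp_path / "production.csv"
    path.write_text(
        "country,product,year,tonnes\n"
        "A,wheat,2011,100\n"
        "A,rice,2011,60\n"
        "A,rice,2011,40\n"
        "B,wheat,2011,50\n"
        "C,maize,2011,0\n"
    )
    return path


@pytest.fixture
def population_csv(tmp_path):
    path = tmp_path / "population.csv"
    path.write_text(
        "country,year,persons\n"
        "A,2011,100\n"
        "B,2011,1000000\n"
        "C,2011,2000000\n"
    )
    return path


def make_population(countries, year=2011, persons=1_000_000):
    return pd.DataFrame(
        {"country": list(countries), "year": year, "persons": float(persons)}
    )
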