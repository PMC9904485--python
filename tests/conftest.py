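import numpy as np
import pandas as pd
import pytest

from monodom.stems import STEM_COLUMNS, PlotGeometry


def make_stem_table(x, y, ba=None, dbh=None, species="GILDE", status="alive",
                    census=1):
    """Minimal canonical stem frame from coordinate arrays."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    df = pd.DataFrame({
        "tag": [f"S{i:04d}" for i in range(n)],
        "species": species,
        "census": census,
        "quadrat_col": np.floor(x / 20),
        "quadrat_row": np.floor(y / 20),
        "x": x, "y": y,
        "dbh": dbh if dbh is not None else np.nan,
        "ba": ba if ba is not None else np.nan,
        "status": status,
        "date": 1995.0,
    })
    return df[STEM_COLUMNS]


@pytest.fixture
def plot():
    return PlotGeometry()


@pytest.fixture
def small_plot():
    return PlotGeometry(width=40.0, height=60.0)


@pytest.fixture(scope="session")
def default_pair():
    """One synthetic census pair at the default expansion rate (cached)."""
    from monodom.simulate import SimulationConfig, simulate

    return simulate(SimulationConfig(seed=42))
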