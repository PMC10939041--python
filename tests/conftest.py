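import numpy as np
import pandas as pd
import pytest

import ordstar as o
from ordstar.model import IID, MRF, ModelSpec, Parametric, PSpline, fit


@pytest.fixture(scope="session")
def lattice8():
    return o.make_lattice_zones(8, 8)


@pytest.fixture(scope="session")
def default_truth_s():
    """Session-shared default study truth (calibration is not free)."""
    return o.default_truth(seed=0)


@pytest.fixture(scope="session")
def default_panel(default_truth_s):
    data, truth = o.gen_panel(default_truth_s, seed=0)
    return data, truth


@pytest.fixture(scope="session")
def small_panel(default_truth_s):
    """Reduced panel (1,000 households x 3 waves) for fast model fits."""
    data, truth = o.gen_panel(default_truth_s, n_households=1000, seed=7)
    return data, truth


@pytest.fixture(scope="session")
def small_fit(small_panel, default_truth_s):
    data, truth = small_panel
    spec = ModelSpec(
        terms=[
            Parametric(["urban", "shock", "wave"]),
            PSpline("dependency_ratio"),
            MRF(),
            IID(),
        ]
    )
    return fit(data, spec, truth.graph)


def toy_panel():
    """Hand-built 8-record panel over 2 zones and 2 waves."""
    df = pd.DataFrame(
        {
            "household": [1, 1, 2, 2, 3, 3, 4, 4],
            "zone": ["A", "A", "A", "A", "B", "B", "B", "B"],
            "wave": [1, 2, 1, 2, 1, 2, 1, 2],
            "fcs": [20.0, 30.0, 40.0, 45.0, 60.0, 70.0, 50.0, 35.5],
            "urban": ["y", "y", "n", "n", "n", "n", "y", "y"],
            "income": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
        }
    )
    return o.PanelDataset(df, factors=["urban"], covariates=["income"])


@pytest.fixture
def toy_data():
    return toy_panel()
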