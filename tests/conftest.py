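import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import cpscreen as cp

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_design() -> cp.ScreenDesign:
    """One-plate screen, 60 features, light cell counts: 10 planted actives."""
    d = cp.make_default_screen(
        seed=11,
        n_compounds=100,
        n_both=4,
        n_activated_only=3,
        n_resting_only=3,
        n_features=60,
    )
    d.cells_per_well_mean = 80.0
    return d


@pytest.fixture(scope="session")
def small_platemap(small_design) -> cp.PlateMap:
    return cp.generate_platemap(small_design, 0)


@pytest.fixture(scope="session")
def small_cells(small_design, small_platemap) -> cp.SingleCellTable:
    return cp.simulate_single_cells(small_design, small_platemap, "resting")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_fingerprints(rng, n_rows=20, n_cols=30, prefix="c"):
    return pd.DataFrame(
        rng.normal(size=(n_rows, n_cols)),
        index=[f"{prefix}{i:03d}" for i in range(n_rows)],
        columns=[f"f{j:03d}" for j in range(n_cols)],
    )
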