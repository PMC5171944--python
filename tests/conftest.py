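import numpy as np
import pandas as pd
import pytest

from fluxconverge.synthetic import SimConfig, generate_dataset


def minimal_row(**overrides):
    """One fully-populated canonical site-table row for fixture files."""
    row = {
        "site_id": "S1", "latitude": 48.0, "longitude": 8.0,
        "climate_zone": "temperate", "years_measured": 2, "data_quality": "high",
        "nep_ec": 250.0, "reco_ec": 1100.0, "gpp_ec": 1350.0,
        "ec_partitioning": "nighttime",
        "npp_wood_aboveground": 300.0, "npp_foliage": 150.0, "npp_fineroot": 50.0,
        "ra_leaf": 250.0, "ra_wood": 150.0,
        "rsoil": 650.0, "rroot": 300.0, "rh_soil": 350.0, "rh_cwd": 50.0,
        "soil_chamber": "nsf", "light_inhibition_considered": True,
        "lai": 4.5, "mean_annual_temperature": 9.0,
    }
    row.update(overrides)
    return row


@pytest.fixture
def two_row_csv(tmp_path):
    rows = [minimal_row(), minimal_row(site_id="S2", latitude=61.0,
                                       climate_zone="boreal", data_quality="fair",
                                       nep_ec=120.0, reco_ec=800.0, gpp_ec=920.0)]
    path = tmp_path / "sites.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default-condition synthetic dataset (31 sites, seed 7)."""
    return generate_dataset(SimConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20161214)
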