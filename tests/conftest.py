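import numpy as np
import pandas as pd
import pytest

from wntscreen import ScreenConfig, WntScreen, simulate_screen
from wntscreen.fixtures import fixture_table
from wntscreen.simulate import ChemicalTruth


@pytest.fixture(scope="session")
def noiseless_config():
    return ScreenConfig(
        n_test_chemicals=20, noise_sigma=0.0, plate_effect_sigma=0.0, seed=3
    )


@pytest.fixture(scope="session")
def small_screen():
    """Small noisy screen with six controls, four replicate days."""
    cfg = ScreenConfig(n_test_chemicals=20, noise_sigma=0.2, seed=1)
    wells, truth = simulate_screen(cfg)
    return cfg, wells, truth


@pytest.fixture(scope="session")
def small_results(small_screen):
    _, wells, _ = small_screen
    return WntScreen.from_dataframe(wells).fit()


@pytest.fixture(scope="session")
def chem_fixture():
    """Twenty molecules from four planted structural families."""
    return fixture_table()


@pytest.fixture()
def plate_csv(tmp_path):
    path = tmp_path / "plate.csv"
    path.write_text(
        "plate_id,well,chemical_id,concentration_uM,firefly,renilla,replicate_day\n"
        "P01,A1,VEHICLE,0,1000,500,1\n"
        "P01,A2,CHEM_X,10,4000,500,1\n"
        "P01,A3,CHEM_Y,10,250,500,1\n"
    )
    return path
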