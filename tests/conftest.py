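import numpy as np
import pandas as pd
import pytest

from ddikit.config import ScenarioConfig
from ddikit.synthetic import generate_scenario


def make_cases(rows):
    """Build a case table from (case_id, region_id, main_dx, [addl...]) tuples."""
    recs = []
    for cid, rid, main, addl in rows:
        recs.append({
            "case_id": cid, "region_id": rid, "year": 2010,
            "main_dx": main, "addl_dx": ";".join(addl),
        })
    return pd.DataFrame(recs, columns=["case_id", "region_id", "year",
                                       "main_dx", "addl_dx"])


def make_regions(rows):
    """Region table from (region_id, population, travel_time_min) tuples."""
    return pd.DataFrame(rows, columns=["region_id", "population",
                                       "travel_time_min"])


@pytest.fixture(scope="session")
def small_scenario():
    """A quick 40-region scenario shared across tests."""
    cfg = ScenarioConfig(n_regions=40, pop_median=600, pop_sigma=0.4,
                         hospitalization_rate=0.4, seed=11)
    return cfg, generate_scenario(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The full default scenario (705 regions, seed 42); generated once.

    This is the costly fixture behind the stochastic-recovery and
    calibration checks; everything that needs the default conditions
    shares it.
    """
    cfg = ScenarioConfig(seed=42)
    return cfg, generate_scenario(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
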