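import warnings

import numpy as np
import pandas as pd
import pytest

from steppebird.config import (DetectionConfig, GeometryConfig,
                               SimulationConfig, SpeciesConfig)

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def small_config():
    """Two-species, two-year configuration kept small for unit tests."""
    return SimulationConfig(
        seed=42, n_plots=20, years=[2016, 2017],
        species=[
            SpeciesConfig("brewers_sparrow", nest_density=5.0, dsr_egg=0.90,
                          dsr_nestling=0.92, nesting_period=19,
                          adult_density=16.0),
            SpeciesConfig("vesper_sparrow", nest_density=6.0, dsr_egg=0.81,
                          dsr_nestling=0.84, nesting_period=15,
                          adult_density=20.0),
        ])


@pytest.fixture(scope="session")
def small_dataset(small_config):
    from steppebird.simulate import simulate_dataset
    return simulate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_histories(n_fledged, n_failed, n_predation, species="sp",
                   start_id=0):
    """Synthetic visit histories with exact fate counts.

    Builds minimal two-visit histories: the terminal visit carries the
    fate (fledged or failed with a cause).
    """
    rows = []
    nid = start_id
    causes = (["predation"] * n_predation
              + ["abandonment"] * (n_failed - n_predation))
    for i in range(n_fledged):
        nid += 1
        rows += [
            dict(nest_id=f"F{nid}", plot_id="P1", year=2016,
                 species=species, visit_day=0, stage="egg",
                 status="active", cause=""),
            dict(nest_id=f"F{nid}", plot_id="P1", year=2016,
                 species=species, visit_day=15, stage="nestling",
                 status="fledged", cause=""),
        ]
    for i in range(n_failed):
        nid += 1
        rows += [
            dict(nest_id=f"X{nid}", plot_id="P1", year=2016,
                 species=species, visit_day=0, stage="egg",
                 status="active", cause=""),
            dict(nest_id=f"X{nid}", plot_id="P1", year=2016,
                 species=species, visit_day=6, stage="egg",
                 status="failed", cause=causes[i]),
        ]
    return pd.DataFrame(rows)
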