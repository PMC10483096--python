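import dataclasses

import pandas as pd
import pytest

from hoiscan import (
    ObservationParams,
    TimeSeriesTable,
    default_study_params,
    generate_study,
)


def make_table(rows):
    """Build a TimeSeriesTable from (microcosm, treatment, rep, day, species,
    density) tuples."""
    return TimeSeriesTable(pd.DataFrame(
        rows,
        columns=["microcosm_id", "treatment", "replicate", "day", "species", "density"],
    ))


def series_table(densities, species="C", treatment="CD", dt=2.0, other=100.0):
    """One microcosm with a prescribed density series for one species and a
    constant-density companion filling out the community."""
    from hoiscan import Treatment

    rows = []
    members = Treatment(treatment).species
    for step, dens in enumerate(densities):
        for sp in members:
            value = dens if sp.value == species else other
            rows.append(("m1", treatment, 1, step * dt, sp.value, value))
    return make_table(rows)


@pytest.fixture(scope="session")
def study_table():
    """Default synthetic 24-microcosm observed study (seed 7)."""
    return generate_study(default_study_params(), obs=ObservationParams(),
                          replicates=4, seed=7)


@pytest.fixture(scope="session")
def latent_study_table():
    """Same study without observation noise (latent densities)."""
    return generate_study(default_study_params(), obs=None, replicates=4, seed=7)


@pytest.fixture()
def noiseless_cd_table():
    """Deterministic additive-LV CD community, no process or counting noise."""
    from hoiscan.validation import two_species_scenario
    from hoiscan import simulate_community

    params = dataclasses.replace(two_species_scenario("none", process_noise_sd=0.0))
    return simulate_community(params)
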