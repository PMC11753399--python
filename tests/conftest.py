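"""Shared fixtures: one default synthetic dataset generated once per session."""

import numpy as np
import pandas as pd
import pytest

from droughtnorms import hormones as hp
from droughtnorms import rainfall as rf
from droughtnorms.simulate import (
    SimulationConfig,
    simulate_gc_samples,
    simulate_individuals,
    simulate_rainfall,
    simulate_survival,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def index_table(default_config):
    """Drought-index table for the default rainfall realization."""
    rain = simulate_rainfall(default_config)
    clim = rf.build_climatology(
        rain, reference_years=range(1996, 2014), expected_reference_years=range(1997, 2014)
    )
    return rf.build_index_table(rain, clim)


@pytest.fixture(scope="session")
def population(default_config, index_table):
    """(females, truth-with-survival, model frame) for the default seed."""
    females, truth = simulate_individuals(default_config)
    samples = simulate_gc_samples(default_config, females, truth, index_table)
    truth = simulate_survival(default_config, truth)
    surv = truth.set_index("female_id")["survived"]
    for fid, rec in females.items():
        rec.survived_el_nino = bool(surv.loc[fid])
        if not rec.survived_el_nino:
            rec.death_window = (pd.Timestamp("2014-05-15"), pd.Timestamp("2016-05-14"))
    selected = pd.concat(
        [hp.select_samples(g) for _, g in samples.groupby("female_id", sort=True)],
        ignore_index=True,
    )
    retained, _ = hp.remove_outliers(selected)
    frame = hp.build_model_frame(retained, females, index_table)
    return females, truth, frame


def make_replicate(config, index_table, seed):
    """One fresh population sharing the default rainfall covariates.

    Individuals, hormone noise and survival outcomes are redrawn from
    ``seed``; the drought-index table (the environmental covariates) is
    held fixed across replicates.
    """
    females, truth = simulate_individuals(config, seed=seed)
    samples = simulate_gc_samples(config, females, truth, index_table, seed=seed + 1)
    truth = simulate_survival(config, truth, seed=seed + 2)
    surv = truth.set_index("female_id")["survived"]
    for fid, rec in females.items():
        rec.survived_el_nino = bool(surv.loc[fid])
        if not rec.survived_el_nino:
            rec.death_window = (pd.Timestamp("2014-05-15"), pd.Timestamp("2016-05-14"))
    selected = pd.concat(
        [hp.select_samples(g) for _, g in samples.groupby("female_id", sort=True)],
        ignore_index=True,
    )
    retained, _ = hp.remove_outliers(selected)
    frame = hp.build_model_frame(retained, females, index_table)
    return females, truth, frame
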