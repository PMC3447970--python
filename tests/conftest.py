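"""Shared fixtures: conditions, ground-truth noise model, simulated data."""

import numpy as np
import pytest

import reachgain as rg
from reachgain.summaries import attach_condition_columns


@pytest.fixture(scope="session")
def conditions():
    return rg.build_conditions()


@pytest.fixture(scope="session")
def condition_by_id(conditions):
    return {c.condition_id: c for c in conditions}


@pytest.fixture(scope="session")
def truth_model():
    return rg.default_sigma_model()


@pytest.fixture(scope="session")
def default_config():
    return rg.GeneratorConfig()


@pytest.fixture(scope="session")
def default_trials(default_config):
    """One full default experiment: 7 subjects x 1080 reaches."""
    return rg.simulate_experiment(default_config, seed=20260920)


@pytest.fixture(scope="session")
def pooled_summaries(default_trials):
    return attach_condition_columns(
        rg.summarize_conditions(default_trials, "pooled"), rg.conditions_frame()
    )


@pytest.fixture(scope="session")
def fitted_model(pooled_summaries):
    return rg.fit_sigma_lines(pooled_summaries)
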