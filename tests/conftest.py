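"""Shared fixtures: synthetic experiments analyzed once per session."""

import numpy as np
import pandas as pd
import pytest

from crowdtpp import SimConfig, generate_experiment, analyze_quants, truth_evaluation


def _tm_errors(exp, fits: pd.DataFrame) -> pd.Series:
    """|fitted Tm − true Tm| for every (protein, condition) fit."""
    ctrl = exp.protein_table.set_index("protein")["tm"]
    treat = exp.truth.set_index(["protein", "crowder"])["tm_treatment"]
    true_tm = np.where(
        fits["condition"] == exp.config.control_name,
        fits["protein"].map(ctrl),
        pd.MultiIndex.from_frame(fits[["protein", "condition"]]).map(treat),
    )
    return (fits["tm"] - true_tm).abs()


@pytest.fixture(scope="session")
def noiseless_run():
    """Default-size experiment without noise, fully analyzed."""
    config = SimConfig(noise_cv=0.0, missing_rate=0.0, seed=1)
    exp = generate_experiment(config)
    result = analyze_quants(exp.quants, control_condition=config.control_name)
    return exp, result


@pytest.fixture(scope="session")
def noisy_run():
    """Default study conditions: 300 proteins, 5% CV noise, seeded."""
    config = SimConfig(seed=1)
    exp = generate_experiment(config)
    result = analyze_quants(exp.quants, control_condition=config.control_name)
    return exp, result


@pytest.fixture(scope="session")
def small_experiment():
    """A fast 40-protein experiment for plumbing tests."""
    config = SimConfig(n_proteins=40, seed=7)
    return generate_experiment(config)


@pytest.fixture
def tm_errors():
    return _tm_errors


@pytest.fixture
def evaluate_calls():
    return truth_evaluation
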