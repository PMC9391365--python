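import numpy as np
import pytest

from midbrainfb.design import build_session_design
from midbrainfb.measures import analyze_subject, summaries_frame
from midbrainfb.preprocess import pca_nuisance
from midbrainfb.simulate import (AgentParams, SubjectParams,
                                 simulate_cohort, simulate_subject)


@pytest.fixture(scope="session")
def default_session():
    return build_session_design()


@pytest.fixture(scope="session")
def default_run(default_session):
    return default_session.run("baseline")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def nuisance_190():
    """A valid nuisance set for the default 190-volume run."""
    r = np.random.default_rng(7)
    csf = 100.0 + r.normal(0.0, 1.0, size=(30, 190))
    motion = r.normal(0.0, 0.05, size=(6, 190))
    return pca_nuisance(csf, motion=motion)


@pytest.fixture(scope="session")
def regulator_params():
    eff = np.array([0.2, 0.85, 0.3, 0.15, 0.4])
    return SubjectParams(
        agent=AgentParams(efficacies=eff, learning_rate=0.4, temperature=0.1),
        regulation_gain=4.0)


@pytest.fixture(scope="session")
def regulator_dataset(regulator_params):
    return simulate_subject(regulator_params, seed=11)


@pytest.fixture(scope="session")
def standard_cohort():
    """40-subject standard-arm cohort (20 regulators / 20 non-regulators)
    with subject summaries; shared across group-level tests."""
    datasets, manifest = simulate_cohort(
        {"regulator": 20, "non_regulator": 20}, seed=1, arm="standard")
    table = summaries_frame([analyze_subject(d) for d in datasets])
    return datasets, manifest, table


@pytest.fixture(scope="session")
def inverted_cohort():
    datasets, manifest = simulate_cohort(
        {"regulator": 9, "non_regulator": 8}, seed=1001, arm="inverted")
    table = summaries_frame([analyze_subject(d) for d in datasets])
    return datasets, manifest, table
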