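import numpy as np
import pandas as pd
import pytest

from cpttrial.cohort import CohortDesignSpec, generate_cohort
from cpttrial.model import (
    NF1ParameterSet,
    SolverConfig,
    TreatmentArm,
    simulate_subject,
)
from cpttrial.stratify import stratify_trial
from cpttrial.trial import run_trial


@pytest.fixture(scope="session")
def normal_params():
    return NF1ParameterSet.normal()


@pytest.fixture(scope="session")
def severe_params():
    """Severe pathological corner: every factor at its worst bound."""
    return NF1ParameterSet(
        c_f_BC=3.0, A_f0=10.0, F_4=0.01, Y_11=0.0, Y_3cb=0.0,
        P_mc=0.0, P_mf=10.0, G_gvc=1e3,
    )


@pytest.fixture(scope="session")
def untreated():
    return TreatmentArm.untreated()


@pytest.fixture(scope="session")
def bmp_arm():
    return TreatmentArm.bmp()


@pytest.fixture(scope="session")
def normal_tc(normal_params, untreated):
    return simulate_subject(normal_params, untreated)


@pytest.fixture(scope="session")
def small_cohort():
    """40-subject cohort for fast module-level tests."""
    return generate_cohort(CohortDesignSpec(n=40, seed=7))


@pytest.fixture(scope="session")
def small_trial(small_cohort):
    return run_trial(small_cohort)


@pytest.fixture(scope="session")
def small_stratified(small_trial):
    return stratify_trial(small_trial)


@pytest.fixture(scope="session")
def default_trial_200():
    """The seeded default 200-subject paired trial (used by acceptance)."""
    cohort = generate_cohort(CohortDesignSpec(n=200, seed=42))
    return run_trial(cohort)


@pytest.fixture(scope="session")
def default_stratified_200(default_trial_200):
    return stratify_trial(default_trial_200)


@pytest.fixture(scope="session")
def separable_fixture():
    """80 subjects where one feature perfectly separates the two classes."""
    rng = np.random.default_rng(11)
    X = pd.DataFrame(
        rng.random((80, 8)),
        columns=[f"f{i}" for i in range(8)],
    )
    y = np.where(X["f3"] > 0.5, "A", "B")
    return X, y
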