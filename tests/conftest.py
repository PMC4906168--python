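import numpy as np
import pytest

from isosurv import ExonCounts, Scenario, SurvivalRecord, simulate_scenario


@pytest.fixture
def toy_records():
    """Six-patient cohort with a mix of events and censoring."""
    return [
        SurvivalRecord("a", 1.0, 1),
        SurvivalRecord("b", 2.0, 0),
        SurvivalRecord("c", 3.0, 1),
        SurvivalRecord("d", 4.5, 1),
        SurvivalRecord("e", 5.0, 0),
        SurvivalRecord("f", 6.0, 1),
    ]


@pytest.fixture
def toy_exon():
    return ExonCounts(
        "ex1",
        ("a", "b", "c", "d", "e", "f"),
        ic=np.array([4, 0, 7, 2, 10, 3]),
        sc=np.array([1, 3, 2, 0, 5, 3]),
        l_inc=2,
        l_skip=1,
    )


@pytest.fixture(scope="session")
def small_null_cohort():
    """Small all-null simulated cohort shared across tests."""
    scenario = Scenario(n_subjects=80, n_exons=30, alt_fraction=0.0,
                        mean_depth=20, seed=11)
    return simulate_scenario(scenario)
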