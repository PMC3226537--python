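import pytest

from asthmacea.cohort_prep import ChildRecord
from asthmacea.costing import default_price_table
from asthmacea.diagnosis import DiagnosisConfig, DiagnosticProfile


@pytest.fixture(scope="session")
def price_table():
    return default_price_table()


@pytest.fixture(scope="session")
def diag_negative():
    return DiagnosisConfig(ics_pos_rev_neg_hyper_neg_rule="negative")


@pytest.fixture(scope="session")
def diag_positive():
    return DiagnosisConfig(ics_pos_rev_neg_hyper_neg_rule="positive")


def make_record(
    id="c-0",
    family_history="PFH",
    trial_arm="intervention",
    airborne=True,
    food=True,
    ics=False,
    symptomatic=False,
    reversibility=False,
    hyperreactivity=False,
    resource_use=None,
):
    """Terse record factory for hand-written micro-fixtures."""
    return ChildRecord(
        id=id,
        family_history=family_history,
        trial_arm=trial_arm,
        airborne_compliant=airborne,
        food_compliant=food,
        profile=DiagnosticProfile(
            ics_use=ics,
            symptomatic=symptomatic,
            reversibility=reversibility,
            hyperreactivity=hyperreactivity,
        ),
        resource_use=resource_use or {},
    )
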