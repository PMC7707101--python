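import pytest

from appendiscore import CohortParameters, PatientRecord, generate_cohort

#: raw values that flip each binary feature on/off under the default policy
RAW_ON = {
    "tenderness_rlq": ("tenderness_rlq", True),
    "rebound_tenderness": ("rebound_tenderness", True),
    "cough_hop_tenderness": ("cough_hop_tenderness", True),
    "continuous_pain": ("continuous_pain", True),
    "nausea_vomiting": ("nausea_vomiting", True),
    "anorexia": ("anorexia", True),
    "migration_of_pain": ("migration_of_pain", True),
    "fever": ("temperature_c", 39.2),
    "wbc_elevated": ("wbc", 14.5),
    "neutrophilia": ("neutrophils_pct", 82.0),
    "crp_elevated": ("crp", 45.0),
    "us_appendicitis": ("us_appendicitis", True),
}
RAW_OFF = {
    "tenderness_rlq": ("tenderness_rlq", False),
    "rebound_tenderness": ("rebound_tenderness", False),
    "cough_hop_tenderness": ("cough_hop_tenderness", False),
    "continuous_pain": ("continuous_pain", False),
    "nausea_vomiting": ("nausea_vomiting", False),
    "anorexia": ("anorexia", False),
    "migration_of_pain": ("migration_of_pain", False),
    "fever": ("temperature_c", 37.1),
    "wbc_elevated": ("wbc", 8.0),
    "neutrophilia": ("neutrophils_pct", 55.0),
    "crp_elevated": ("crp", 4.0),
    "us_appendicitis": ("us_appendicitis", False),
}


def make_patient(id="p1", **overrides):
    """A fully recorded patient with every binary feature negative."""
    base = dict(
        id=id, age=10.0, sex="male", duration_h=24.0,
        continuous_pain=False, nausea_vomiting=False, anorexia=False,
        migration_of_pain=False, tenderness_rlq=False, rebound_tenderness=False,
        cough_hop_tenderness=False, temperature_c=37.1, wbc=8.0,
        neutrophils_abs=4.0, neutrophils_pct=55.0, crp=4.0,
        us_appendicitis=False, outcome="no_appendicitis",
    )
    base.update(overrides)
    return PatientRecord(**base)


def patient_from_indicators(indicators: dict, id="p1", outcome="no_appendicitis"):
    """Build a patient whose derived feature vector equals ``indicators``."""
    overrides = {}
    for feature, on in indicators.items():
        field, value = (RAW_ON if on else RAW_OFF)[feature]
        overrides[field] = value
    if indicators.get("neutrophilia"):
        overrides["neutrophils_abs"] = 9.5
    return make_patient(id=id, outcome=outcome, **overrides)


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded default-parameter synthetic cohort (463 patients)."""
    return generate_cohort(CohortParameters(seed=7))


@pytest.fixture(scope="session")
def complete_cohort(default_cohort):
    return [p for p in default_cohort
            if p.wbc is not None and p.us_appendicitis is not None]
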