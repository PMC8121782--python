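import pytest
from hypothesis import settings

from thalscore import (
    Cohort,
    Patient,
    Severity,
    default_scoring_system,
    load_reference_frequencies,
)

settings.register_profile("default", derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def system():
    return default_scoring_system()


@pytest.fixture(scope="session")
def snps(system):
    return {snp.snp_id: snp for snp in system.snps}


@pytest.fixture(scope="session")
def freq_table():
    return load_reference_frequencies()


def make_patient(pid, g766432, g9399137, g72872548, severity):
    return Patient(
        patient_id=pid,
        genotypes={
            "rs766432": g766432,
            "rs9399137": g9399137,
            "rs72872548": g72872548,
        },
        severity=Severity.parse(severity),
    )


@pytest.fixture
def tiny_cohort():
    """Three patients spanning the score range, one with a missing call."""
    return Cohort(
        patients=[
            make_patient("P1", "AA", "TT", "CC", "severe"),
            make_patient("P2", "CC", "CC", "AA", "mild"),
            make_patient("P3", "AC", None, "AC", "moderate"),
        ],
        name="tiny",
    )
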