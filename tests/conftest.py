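import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from methpanel import (
    CohortTable,
    MarkerPanel,
    PatientRecord,
    SampleRecord,
    default_panel,
)


@pytest.fixture(scope="session")
def panel32() -> MarkerPanel:
    return default_panel()


def make_sample(panel, pid, stype, positives=(), magnitude=5.0, control_ok=True):
    """A sample with the given markers positive at a fixed magnitude."""
    signals = {m: (magnitude if m in positives else 0.0) for m in panel}
    return SampleRecord(pid, stype, signals, control_ok=control_ok)


def make_cohort(panel, samples, diagnoses):
    """Cohort from samples plus a {patient_id: (diagnosis, group)} map."""
    patients = {
        pid: PatientRecord(pid, diag, group)
        for pid, (diag, group) in diagnoses.items()
    }
    return CohortTable(panel=panel, samples=samples, patients=patients)


@pytest.fixture()
def tiny_cohort(panel32):
    """Two patients, one case (10 positive markers) one control (2)."""
    markers = list(panel32)
    samples = [
        make_sample(panel32, "case1", "DRE", markers[:10], magnitude=3.2),
        make_sample(panel32, "ctrl1", "DRE", markers[:2], magnitude=1.0),
    ]
    return make_cohort(
        panel32, samples, {"case1": ("case", 1), "ctrl1": ("control", 0)}
    )
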