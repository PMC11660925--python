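import numpy as np
import pandas as pd
import pytest

from msphase.registry import (
    Cohort,
    EDSSObservation,
    PatientRecord,
    RelapseEvent,
    TreatmentEpisode,
)


@pytest.fixture
def fig_patient() -> tuple[PatientRecord, list[int]]:
    """The worked-example patient: SPMS diagnosed at day 0 after an RRMS
    course, one relapse 100 days before the diagnosis and one at day 6547,
    follow-up to day 6721."""
    p = PatientRecord(
        patient_id="fig",
        sex="female",
        onset_day=-1500,
        rrms_dx_day=-1200,
        spms_dx_day=0,
        end_day=6721,
        end_reason="admin_censor",
        age_at_onset=30.0,
    )
    return p, [-100, 6547]


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Three hand-built patients: one RRMS-only, one nrSPMS converter, one
    rSPMS converter who dies."""
    patients = [
        PatientRecord("a", "female", 0, 100, None, 6000, "admin_censor", 30.0),
        PatientRecord("b", "male", 50, 400, 3000, 6500, "admin_censor", 40.0),
        PatientRecord("c", "female", 0, 200, 2000, 5000, "death", 35.0),
    ]
    relapses = [
        RelapseEvent("a", 50),
        RelapseEvent("a", 900),
        RelapseEvent("b", 300),
        RelapseEvent("c", 1900),
        RelapseEvent("c", 4000),
    ]
    edss = [
        EDSSObservation("a", 100, 1.0),
        EDSSObservation("a", 2000, 2.0),
        EDSSObservation("b", 400, 2.0),
        EDSSObservation("b", 3000, 4.5),
        EDSSObservation("c", 200, 1.5),
        EDSSObservation("c", 2000, 5.0),
        EDSSObservation("c", 4500, 6.5),
    ]
    treatments = [
        TreatmentEpisode("a", "interferon beta-1a", 120, 2000),
        TreatmentEpisode("b", "natalizumab", 500, 2500),
        TreatmentEpisode("c", "teriflunomide", 250, 1800),
    ]
    return Cohort(patients, relapses, edss, treatments)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_patient(rng: np.random.Generator, i: int) -> tuple[PatientRecord, list[int]]:
    """A random patient with an SPMS diagnosis and a random relapse history,
    used for classifier-oracle comparisons."""
    dx = int(rng.integers(0, 200))
    spms = dx + int(rng.integers(0, 1500))
    end = spms + int(rng.integers(0, 3000))
    n_rel = int(rng.integers(0, 10))
    relapses = sorted(int(rng.integers(dx - 900, end + 1)) for _ in range(n_rel))
    p = PatientRecord(
        patient_id=f"r{i}",
        sex="male" if i % 2 else "female",
        onset_day=dx - 400,
        rrms_dx_day=dx,
        spms_dx_day=spms if rng.random() < 0.8 else None,
        end_day=end,
        end_reason="admin_censor",
        age_at_onset=30.0 + float(rng.random()) * 10,
    )
    return p, [r for r in relapses if r <= end]
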