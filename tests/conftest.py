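"""Shared fixtures: tiny deterministic corpora and record factories."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest

from cadval.his_extract import ReportRecord, SessionHeader
from cadval.ingest import AIResult
from cadval.synthetic import GeneratorConfig, generate_corpus

T0 = datetime(2020, 11, 5, 8, 0, 0)


def make_ai(
    uid: str = "1.2.3",
    patient: str = "PT1",
    study_time: datetime = T0,
    status: int = 0,
) -> AIResult:
    return AIResult(
        study_uid=uid, patient_id=patient, study_time=study_time, abnormal_status=status
    )


def make_report(
    patient: str = "PT1",
    session_id: str = "S1",
    check_in: datetime = T0 - timedelta(hours=2),
    check_out: datetime = T0 + timedelta(hours=30),
    report_time: datetime = T0 + timedelta(hours=2),
    service_id: str = "CXR",
    description: str = "",
) -> ReportRecord:
    header = SessionHeader(
        session_id=session_id,
        patient_id=patient,
        check_in_time=check_in,
        check_out_time=check_out,
    )
    return ReportRecord(
        session=header,
        service_id=service_id,
        report_time=report_time,
        description=description,
    )


def random_linkage_problem(rng: np.random.Generator, max_records: int = 5):
    """A small random matching problem: few patients, jittered times and
    windows, delays spanning both sides of the 24 h limit."""
    patients = [f"P{k}" for k in range(rng.integers(1, 4))]
    ais = []
    for i in range(rng.integers(0, max_records + 1)):
        ais.append(
            make_ai(
                uid=f"uid-{i}",
                patient=str(rng.choice(patients)),
                study_time=T0 + timedelta(hours=float(rng.uniform(-36, 36))),
            )
        )
    reports = []
    for j in range(rng.integers(0, max_records + 1)):
        anchor = T0 + timedelta(hours=float(rng.uniform(-36, 36)))
        reports.append(
            make_report(
                patient=str(rng.choice(patients)),
                session_id=f"S{j}",
                check_in=anchor - timedelta(hours=float(rng.uniform(0, 12))),
                check_out=anchor + timedelta(hours=float(rng.uniform(0, 48))),
                report_time=anchor + timedelta(hours=float(rng.uniform(-40, 40))),
            )
        )
    return ais, reports


@pytest.fixture(scope="session")
def small_corpus():
    """A mid-sized corpus with all noise channels active."""
    return generate_corpus(GeneratorConfig(n_patients=400, seed=11))


@pytest.fixture(scope="session")
def clean_corpus():
    """No nuisance records, no unmatched records, no out-of-window reports:
    the downstream pipeline must recover the truth table exactly."""
    config = GeneratorConfig(
        n_patients=300,
        unmatched_report_rate=0.0,
        unmatched_study_rate=0.0,
        nuisance_modality_rate=0.0,
        out_of_window_rate=0.0,
        seed=23,
    )
    return generate_corpus(config)
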