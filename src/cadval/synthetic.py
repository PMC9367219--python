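"""Synthetic hospital corpus generator.

Real PACS/HIS data from a clinical validation cannot be shared, so every
downstream stage is exercised on a generated corpus with the same
statistical structure: a population of patients with one or more imaging
studies, a binary abnormal truth per study at a configurable prevalence, AI
predictions drawn per-study as Bernoulli(sensitivity) for abnormal truths
and Bernoulli(1 - specificity) for normal truths, one HIS session per
study whose window contains the study time, and a radiology report whose
DESCRIPTION is built from the active normal-description template set
(normal studies) or has at least one region's sentence replaced by an
abnormal phrase (abnormal studies).

Imperfections of real hospital data are injected at configurable rates:
studies whose report never appears in HIS, reports delayed past the 24-hour
protocol window, orphan reports for patients with no study, non-CXR
modalities (CT/MR/US of ABDOMEN/SKULL), and non-CXR service reports inside
sessions.  The hidden truth table records, for every study, the abnormal
status and whether the study is expected to survive filtering + linkage.

The default configuration mirrors the deployment population the harness
was built to reproduce: ~6,285 studies of 5,989 patients over two months,
27.9% abnormal prevalence, classifier sensitivity 68.6% and specificity
83.9%, and a few percent of records failing linkage on each side.

Generation is exactly reproducible: the same seed and configuration yield a
byte-identical corpus on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .his_extract import ReportRecord, SessionHeader
from .ingest import AIResult, StudyMeta
from .labeler import REGIONS, TemplateSet

#: First day of the simulated two-month validation window.
PERIOD_START = datetime(2020, 11, 1)
PERIOD_DAYS = 61

NUISANCE_MODALITIES = ("CT", "MR", "US")
NUISANCE_BODY_PARTS = ("ABDOMEN", "SKULL")
NUISANCE_SERVICE_IDS = ("SVC-LAB", "SVC-US")

#: Abnormal-finding phrases per region.  Invented wording; none contains a
#: normal template as a substring, so substituting one flips the region.
ABNORMAL_PHRASES = {
    "chest_wall": (
        "gãy xương sườn số 5 bên phải",
        "gãy xương đòn trái",
    ),
    "pleura": (
        "tràn dịch màng phổi phải lượng nhiều",
        "tràn khí màng phổi trái",
    ),
    "lung": (
        "nốt mờ thùy trên phổi phải",
        "đám mờ không đồng nhất hai phổi",
    ),
    "mediastinum": (
        "bóng tim to, chỉ số tim ngực 0.65",
        "trung thất rộng",
    ),
}


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-population and noise parameters of the synthetic corpus.

    Defaults reproduce the reference deployment population (about 6,285
    CXR studies of 5,989 patients, 27.9% abnormal, sensitivity 0.686,
    specificity 0.839, ~5-6% of records failing linkage on each side).
    """

    n_patients: int = 5989
    studies_per_patient_mean: float = 6285 / 5989
    prevalence: float = 0.279
    sensitivity: float = 0.686
    specificity: float = 0.839
    cxr_service_id: str = "CXR-MOH"
    report_delay_max_hours: float = 24.0
    unmatched_report_rate: float = 0.060
    unmatched_study_rate: float = 0.046
    nuisance_modality_rate: float = 0.05
    out_of_window_rate: float = 0.010
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.studies_per_patient_mean < 1:
            raise ConfigurationError("studies_per_patient_mean must be >= 1")
        for name in (
            "prevalence",
            "sensitivity",
            "specificity",
            "unmatched_report_rate",
            "unmatched_study_rate",
            "nuisance_modality_rate",
            "out_of_window_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be a probability, got {value}")
        if not 0 < self.report_delay_max_hours <= 24:
            raise ConfigurationError("report_delay_max_hours must be in (0, 24]")
        if not self.cxr_service_id:
            raise ConfigurationError("cxr_service_id must be non-empty")


@dataclass
class SyntheticCorpus:
    """In-memory synthetic hospital corpus plus its hidden truth table."""

    config: GeneratorConfig
    studies: list[StudyMeta]
    predictions: list[AIResult]
    sessions: list[tuple[SessionHeader, list[ReportRecord]]]
    truth: pd.DataFrame = field(repr=False)  # study_uid, truth, expect_match


def _whole_seconds(dt: datetime) -> datetime:
    return dt.replace(microsecond=0)


def _normal_description(rng: np.random.Generator, templates: TemplateSet) -> str:
    sentences = [
        str(rng.choice(templates.region_templates[region])) for region in REGIONS
    ]
    return _assemble(rng, sentences)


def _abnormal_description(rng: np.random.Generator, templates: TemplateSet) -> str:
    n_abnormal = 1 + rng.binomial(len(REGIONS) - 1, 0.25)
    abnormal_regions = set(
        rng.choice(len(REGIONS), size=n_abnormal, replace=False).tolist()
    )
    sentences = []
    for k, region in enumerate(REGIONS):
        if k in abnormal_regions:
            sentences.append(str(rng.choice(ABNORMAL_PHRASES[region])))
        else:
            sentences.append(str(rng.choice(templates.region_templates[region])))
    return _assemble(rng, sentences)


def _assemble(rng: np.random.Generator, sentences: list[str]) -> str:
    """Join region sentences with benign formatting noise (case, whitespace,
    separators) that the labeler's normalization must absorb."""
    sep = str(rng.choice([". ", ".\n", " .  "]))
    text = sep.join(sentences)
    roll = rng.random()
    if roll < 0.15:
        text = text.upper()
    if rng.random() < 0.2:
        text = "KẾT QUẢ:  " + text
    return text


def generate_corpus(
    config: GeneratorConfig, templates: TemplateSet | None = None
) -> SyntheticCorpus:
    """Generate studies, predictions, HIS sessions, and the truth table.

    Every non-nuisance study that is neither dropped from HIS nor delayed
    out of window has exactly one report satisfying all three match
    conditions; session windows of one patient are disjoint, so linkage on
    a clean corpus is unambiguous and recovers the truth table exactly.
    """
    templates = templates or TemplateSet.default()
    rng = np.random.default_rng(config.seed)

    studies: list[StudyMeta] = []
    predictions: list[AIResult] = []
    sessions: list[tuple[SessionHeader, list[ReportRecord]]] = []
    truth_rows: list[dict] = []
    n_orphan = 0

    for p in range(config.n_patients):
        patient_id = f"PT{p:06d}"
        n_studies = 1 + rng.poisson(config.studies_per_patient_mean - 1)
        study_time = PERIOD_START + timedelta(
            seconds=float(rng.uniform(0, PERIOD_DAYS * 86400))
        )
        for s in range(n_studies):
            if s > 0:  # disjoint session windows within a patient
                study_time = study_time + timedelta(
                    hours=float(rng.uniform(96, 240))
                )
            study_time = _whole_seconds(study_time)
            study_uid = f"1.2.840.99999.{p}.{s}"
            nuisance = rng.random() < config.nuisance_modality_rate
            if nuisance:
                modality = str(rng.choice(NUISANCE_MODALITIES))
                body_part = str(rng.choice(NUISANCE_BODY_PARTS))
            else:
                modality = str(rng.choice(["DX", "DX", "DX", "CR", "DR"]))
                body_part = str(rng.choice(["CHEST", "CHEST", "THORAX"]))

            truth = int(rng.random() < config.prevalence)
            if truth:
                status = int(rng.random() < config.sensitivity)
            else:
                status = int(rng.random() >= config.specificity)
            probability = float(
                rng.uniform(0.501, 0.999) if status else rng.uniform(0.001, 0.499)
            )

            studies.append(
                StudyMeta(
                    study_uid=study_uid,
                    patient_id=patient_id,
                    study_time=study_time,
                    modality=modality,
                    body_part=body_part,
                )
            )
            predictions.append(
                AIResult(
                    study_uid=study_uid,
                    patient_id=patient_id,
                    study_time=study_time,
                    abnormal_status=status,
                    abnormal_probability=probability,
                )
            )

            header = SessionHeader(
                session_id=f"SES{p:06d}-{s}",
                patient_id=patient_id,
                check_in_time=_whole_seconds(
                    study_time - timedelta(hours=float(rng.uniform(0.5, 4)))
                ),
                check_out_time=_whole_seconds(
                    study_time + timedelta(hours=float(rng.uniform(6, 36)))
                ),
            )
            reports: list[ReportRecord] = []

            no_report = rng.random() < config.unmatched_study_rate
            out_of_window = rng.random() < config.out_of_window_rate
            expect_match = not (nuisance or no_report or out_of_window)

            if not nuisance and not no_report:
                if out_of_window:
                    delay = timedelta(hours=24 + float(rng.uniform(1, 24)))
                else:
                    delay = timedelta(
                        seconds=float(
                            rng.uniform(30, config.report_delay_max_hours * 3600)
                        )
                    )
                description = (
                    _abnormal_description(rng, templates)
                    if truth
                    else _normal_description(rng, templates)
                )
                reports.append(
                    ReportRecord(
                        session=header,
                        service_id=config.cxr_service_id,
                        report_time=_whole_seconds(study_time + delay),
                        description=description,
                    )
                )

            if rng.random() < 0.25:  # unrelated service inside the session
                reports.append(
                    ReportRecord(
                        session=header,
                        service_id=str(rng.choice(NUISANCE_SERVICE_IDS)),
                        report_time=_whole_seconds(
                            header.check_in_time + timedelta(minutes=30)
                        ),
                        description="siêu âm ổ bụng không phát hiện bất thường",
                    )
                )
            sessions.append((header, reports))

            # orphan CXR report: a patient present in HIS but absent in PACS
            if rng.random() < config.unmatched_report_rate:
                orphan_pid = f"PX{n_orphan:06d}"
                orphan_time = _whole_seconds(
                    PERIOD_START
                    + timedelta(seconds=float(rng.uniform(0, PERIOD_DAYS * 86400)))
                )
                orphan_header = SessionHeader(
                    session_id=f"SEX{n_orphan:06d}",
                    patient_id=orphan_pid,
                    check_in_time=orphan_time,
                    check_out_time=orphan_time + timedelta(hours=12),
                )
                sessions.append(
                    (
                        orphan_header,
                        [
                            ReportRecord(
                                session=orphan_header,
                                service_id=config.cxr_service_id,
                                report_time=orphan_time + timedelta(hours=2),
                                description=_normal_description(rng, templates),
                            )
                        ],
                    )
                )
                n_orphan += 1

            truth_rows.append(
                {
                    "study_uid": study_uid,
                    "truth": truth,
                    "expect_match": expect_match,
                }
            )

    truth = pd.DataFrame(truth_rows, columns=["study_uid", "truth", "expect_match"])
    return SyntheticCorpus(
        config=config,
        studies=studies,
        predictions=predictions,
        sessions=sessions,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# serialization


def write_his_xml(corpus: SyntheticCorpus, directory: str | Path) -> list[Path]:
    """Write one session XML file per session; returns the paths written."""
    from xml.etree import ElementTree as ET

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for header, reports in corpus.sessions:
        root = ET.Element(
            "SESSION",
            {
                "SESSION_ID": header.session_id,
                "PATIENT_ID": header.patient_id,
                "CHECK_IN_TIME": header.check_in_time.isoformat(),
                "CHECK_OUT_TIME": header.check_out_time.isoformat(),
            },
        )
        for report in reports:
            elem = ET.SubElement(
                root,
                "REPORT",
                {
                    "SERVICE_ID": report.service_id,
                    "REPORT_TIME": report.report_time.isoformat(),
                },
            )
            ET.SubElement(elem, "DESCRIPTION").text = report.description
        path = directory / f"{header.session_id}.xml"
        try:
            ET.ElementTree(root).write(path, encoding="utf-8", xml_declaration=True)
        except OSError as exc:
            raise OSError(f"failed writing session file {path}: {exc}") from exc
        paths.append(path)
    return paths


def write_study_metadata(
    corpus: SyntheticCorpus, directory: str | Path, as_dicom: bool = False
) -> list[Path]:
    """Write study metadata as minimal DICOM files or one CSV table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not corpus.studies:
        return []
    if not as_dicom:
        path = directory / "studies.csv"
        frame = pd.DataFrame(
            [
                {
                    "study_uid": s.study_uid,
                    "patient_id": s.patient_id,
                    "study_time": s.study_time.isoformat(),
                    "modality": s.modality,
                    "body_part": s.body_part,
                }
                for s in corpus.studies
            ],
            columns=["study_uid", "patient_id", "study_time", "modality", "body_part"],
        )
        frame.to_csv(path, index=False)
        return [path]

    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian

    paths = []
    for s in corpus.studies:
        file_meta = FileMetaDataset()
        file_meta.MediaStorageSOPClassUID = "1.2.840.10008.5.1.4.1.1.1"  # CR storage
        file_meta.MediaStorageSOPInstanceUID = s.study_uid + ".0"
        file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = file_meta
        ds.SOPClassUID = file_meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = s.study_uid
        ds.PatientID = s.patient_id
        ds.Modality = s.modality
        ds.BodyPartExamined = s.body_part
        ds.StudyDate = s.study_time.strftime("%Y%m%d")
        ds.StudyTime = s.study_time.strftime("%H%M%S")
        path = directory / f"{s.study_uid}.dcm"
        try:
            ds.save_as(path, enforce_file_format=True)
        except OSError as exc:
            raise OSError(f"failed writing DICOM file {path}: {exc}") from exc
        paths.append(path)
    return paths


def write_predictions(corpus: SyntheticCorpus, path: str | Path) -> Path:
    """Write the AI prediction table (study_uid, probability, status)."""
    path = Path(path)
    frame = pd.DataFrame(
        [
            {
                "study_uid": r.study_uid,
                "abnormal_probability": r.abnormal_probability,
                "abnormal_status": r.abnormal_status,
            }
            for r in corpus.predictions
        ],
        columns=["study_uid", "abnormal_probability", "abnormal_status"],
    )
    frame.to_csv(path, index=False)
    return path


def write_truth(corpus: SyntheticCorpus, path: str | Path) -> Path:
    """Write the hidden truth table (study_uid, truth, expect_match)."""
    path = Path(path)
    corpus.truth.to_csv(path, index=False)
    return path


def write_corpus(
    corpus: SyntheticCorpus, directory: str | Path, as_dicom: bool = False
) -> dict[str, object]:
    """Write the whole corpus under ``directory`` in the standard layout."""
    directory = Path(directory)
    study_dir = directory / ("dicom" if as_dicom else "studies")
    return {
        "sessions": write_his_xml(corpus, directory / "sessions"),
        "studies": write_study_metadata(corpus, study_dir, as_dicom=as_dicom),
        "predictions": write_predictions(corpus, directory / "predictions.csv"),
        "truth": write_truth(corpus, directory / "truth.csv"),
    }


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    return replace(config, seed=seed)
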