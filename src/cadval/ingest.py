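"""Study-metadata ingestion: CXR filtering and attachment of AI predictions.

A hospital PACS stores every imaging study as DICOM; only chest radiographs
(modality CR/DR/DX, body part CHEST/THORAX) are eligible for the abnormality
classifier.  This module reads study metadata either from DICOM files or from
a flat delimited table, applies the CXR filter, and joins each surviving study
with the AI verdict from a prediction table, yielding :class:`AIResult`
records ready for matching against radiology reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Modality tokens accepted by the CXR adapter.
CXR_MODALITIES = frozenset({"CR", "DR", "DX"})
#: Body-part tokens accepted by the CXR adapter.
CXR_BODY_PARTS = frozenset({"CHEST", "THORAX"})

#: Probability threshold above which (strictly) a study is called abnormal.
DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class StudyMeta:
    """Identifying metadata of one imaging study.

    ``study_uid`` doubles as the DICOM StudyInstanceUID; ``modality`` and
    ``body_part`` carry the raw MODALITY / BODY_PART_EXAMINED tag values.
    """

    study_uid: str
    patient_id: str
    study_time: datetime
    modality: str
    body_part: str


@dataclass(frozen=True)
class AIResult:
    """Binary AI verdict attached to a CXR study.

    ``abnormal_status`` is 1 for abnormal, 0 for normal.  When the source
    table carries probabilities, the status is derived with a strict
    ``probability > threshold`` rule.
    """

    study_uid: str
    patient_id: str
    study_time: datetime
    abnormal_status: int
    abnormal_probability: float | None = None


def is_cxr(
    meta: StudyMeta,
    modalities: frozenset[str] = CXR_MODALITIES,
    body_parts: frozenset[str] = CXR_BODY_PARTS,
) -> bool:
    """Return True iff the study is a chest radiograph.

    Tokens are compared exactly after stripping surrounding whitespace and
    upper-casing; DICOM tag values are not standardised across sites, so the
    accepted sets are parameters with the conventional defaults.
    """
    modality = meta.modality.strip().upper() if meta.modality else ""
    body_part = meta.body_part.strip().upper() if meta.body_part else ""
    if not modality or not body_part:
        logger.debug("study %s missing modality/body part", meta.study_uid)
        return False
    return modality in modalities and body_part in body_parts


def _parse_timestamp(value: object) -> datetime:
    if isinstance(value, datetime):
        return value
    return datetime.fromisoformat(str(value))


def _studies_from_table(path: Path) -> list[StudyMeta]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["study_uid", "patient_id", "study_time", "modality", "body_part"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    studies: list[StudyMeta] = []
    for row in frame.itertuples(index=False):
        try:
            if not row.study_uid or not row.patient_id:
                raise ValueError("empty study_uid or patient_id")
            studies.append(
                StudyMeta(
                    study_uid=row.study_uid,
                    patient_id=row.patient_id,
                    study_time=_parse_timestamp(row.study_time),
                    modality=row.modality,
                    body_part=row.body_part,
                )
            )
        except (ValueError, TypeError) as exc:
            logger.warning("%s: skipping malformed row %r (%s)", path, row, exc)
    return studies


def _studies_from_dicom(path: Path) -> list[StudyMeta]:
    import pydicom

    studies: list[StudyMeta] = []
    for fname in sorted(path.glob("*.dcm")):
        try:
            ds = pydicom.dcmread(fname, stop_before_pixels=True)
            study_uid = str(ds.StudyInstanceUID)
            patient_id = str(ds.PatientID)
            date = str(ds.StudyDate)
            time = str(ds.StudyTime)
            study_time = datetime.strptime(date + time.split(".")[0], "%Y%m%d%H%M%S")
            studies.append(
                StudyMeta(
                    study_uid=study_uid,
                    patient_id=patient_id,
                    study_time=study_time,
                    modality=str(getattr(ds, "Modality", "")),
                    body_part=str(getattr(ds, "BodyPartExamined", "")),
                )
            )
        except Exception as exc:  # unreadable file: skip, never fatal
            logger.warning("%s: unreadable DICOM file skipped (%s)", fname, exc)
    return studies


def load_studies(source: str | Path, dialect: str = "table") -> list[StudyMeta]:
    """Read study metadata from ``source``.

    ``dialect='table'`` expects a UTF-8 CSV with columns
    study_uid, patient_id, study_time, modality, body_part;
    ``dialect='dicom'`` expects a directory of ``*.dcm`` files.
    Unreadable entries are logged and skipped.
    """
    source = Path(source)
    if dialect == "table":
        studies = _studies_from_table(source)
    elif dialect == "dicom":
        studies = _studies_from_dicom(source)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not studies:
        logger.warning("%s: no studies loaded", source)
    return studies


def attach_predictions(
    studies: Sequence[StudyMeta],
    predictions: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    modalities: frozenset[str] = CXR_MODALITIES,
    body_parts: frozenset[str] = CXR_BODY_PARTS,
) -> list[AIResult]:
    """Join CXR studies with their AI predictions.

    ``predictions`` must be keyed by ``study_uid`` and carry
    ``abnormal_probability`` and/or ``abnormal_status``.  Non-CXR studies are
    filtered out first; CXR studies without a prediction are logged and
    dropped.  An optional boolean ``valid`` column (the PA-view pre-filter
    verdict) drops rows marked invalid.

    Raises ``ValueError`` on duplicate study_uid keys — the join would be
    ambiguous.
    """
    if "study_uid" not in predictions.columns:
        raise ValueError("prediction table lacks a study_uid column")
    if predictions["study_uid"].duplicated().any():
        dupes = predictions.loc[predictions["study_uid"].duplicated(), "study_uid"]
        raise ValueError(f"duplicate study_uid in predictions: {sorted(set(dupes))}")

    table = predictions.set_index("study_uid")
    results: list[AIResult] = []
    for study in studies:
        if not is_cxr(study, modalities, body_parts):
            continue
        if study.study_uid not in table.index:
            logger.warning("study %s has no prediction; dropped", study.study_uid)
            continue
        row = table.loc[study.study_uid]
        if "valid" in table.columns and not pd.isna(row["valid"]):
            if not bool(int(row["valid"])):
                logger.info("study %s rejected by PA pre-filter", study.study_uid)
                continue
        probability: float | None = None
        if "abnormal_probability" in table.columns and not pd.isna(
            row["abnormal_probability"]
        ):
            probability = float(row["abnormal_probability"])
            status = int(probability > threshold)  # strictly above
        elif "abnormal_status" in table.columns and not pd.isna(row["abnormal_status"]):
            status = int(row["abnormal_status"])
            if status not in (0, 1):
                raise ValueError(
                    f"study {study.study_uid}: abnormal_status must be 0/1, got {status}"
                )
        else:
            raise ValueError(
                "prediction table needs abnormal_probability or abnormal_status"
            )
        results.append(
            AIResult(
                study_uid=study.study_uid,
                patient_id=study.patient_id,
                study_time=study.study_time,
                abnormal_status=status,
                abnormal_probability=probability,
            )
        )
    return results


def ai_results_to_frame(results: Iterable[AIResult]) -> pd.DataFrame:
    """Serialize AI results to a flat table (ISO-8601 timestamps)."""
    return pd.DataFrame(
        [
            {
                "study_uid": r.study_uid,
                "patient_id": r.patient_id,
                "study_time": r.study_time.isoformat(),
                "abnormal_status": r.abnormal_status,
                "abnormal_probability": (
                    "" if r.abnormal_probability is None else r.abnormal_probability
                ),
            }
            for r in results
        ],
        columns=[
            "study_uid",
            "patient_id",
            "study_time",
            "abnormal_status",
            "abnormal_probability",
        ],
    )


def frame_to_ai_results(frame: pd.DataFrame) -> list[AIResult]:
    results = []
    for row in frame.itertuples(index=False):
        prob = getattr(row, "abnormal_probability", "")
        prob_val = None if prob in ("", None) or pd.isna(prob) else float(prob)
        results.append(
            AIResult(
                study_uid=str(row.study_uid),
                patient_id=str(row.patient_id),
                study_time=_parse_timestamp(row.study_time),
                abnormal_status=int(row.abnormal_status),
                abnormal_probability=prob_val,
            )
        )
    return results
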