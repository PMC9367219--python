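"""Extraction of radiology reports from HIS session XML exports.

Each examination session is one XML file carrying a header
(SESSION_ID, PATIENT_ID, CHECK_IN_TIME, CHECK_OUT_TIME) and any number of
report elements (SERVICE_ID, REPORT_TIME, DESCRIPTION).  Chest-radiograph
reports are selected by exact SERVICE_ID equality against the site's
reserved CXR service code, which is site configuration and has no default.

Schema (self-defined; the attribute vocabulary mirrors the hospital export)::

    <SESSION SESSION_ID=".." PATIENT_ID=".." CHECK_IN_TIME=".." CHECK_OUT_TIME="..">
      <REPORT SERVICE_ID=".." REPORT_TIME="..">
        <DESCRIPTION>free text</DESCRIPTION>
      </REPORT>
    </SESSION>

Timestamps are timezone-naive ISO 8601 (``YYYY-MM-DDTHH:MM:SS``).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence
from xml.etree import ElementTree as ET

import pandas as pd


class SessionParseError(ValueError):
    """Raised when a session file is malformed or violates an invariant."""


@dataclass(frozen=True)
class SessionHeader:
    session_id: str
    patient_id: str
    check_in_time: datetime
    check_out_time: datetime

    def __post_init__(self) -> None:
        if self.check_in_time > self.check_out_time:
            raise SessionParseError(
                f"session {self.session_id}: CHECK_IN_TIME after CHECK_OUT_TIME"
            )


@dataclass(frozen=True)
class ReportRecord:
    """One radiology report, with its session header attached.

    ``description`` is preserved exactly as decoded from the file; no text
    normalization happens at parse time.
    """

    session: SessionHeader
    service_id: str
    report_time: datetime
    description: str


_HEADER_ATTRS = ("SESSION_ID", "PATIENT_ID", "CHECK_IN_TIME", "CHECK_OUT_TIME")
_REPORT_ATTRS = ("SERVICE_ID", "REPORT_TIME")


def _require(attrs: dict, names: Sequence[str], path: Path) -> list[str]:
    values = []
    for name in names:
        if name not in attrs:
            raise SessionParseError(f"{path}: missing required attribute {name}")
        values.append(attrs[name])
    return values


def parse_session(xml_path: str | Path) -> tuple[SessionHeader, list[ReportRecord]]:
    """Parse one session XML file into its header and all contained reports.

    All reports are returned regardless of SERVICE_ID; CXR selection is a
    separate step (:func:`filter_cxr_reports`).  Malformed XML, a missing
    required attribute, or an inverted check-in/check-out window raise
    :class:`SessionParseError` naming the file.
    """
    xml_path = Path(xml_path)
    try:
        root = ET.parse(xml_path).getroot()
    except ET.ParseError as exc:
        raise SessionParseError(f"{xml_path}: malformed XML ({exc})") from exc
    if root.tag != "SESSION":
        raise SessionParseError(f"{xml_path}: root element must be SESSION, got {root.tag}")

    sid, pid, t_in, t_out = _require(root.attrib, _HEADER_ATTRS, xml_path)
    try:
        header = SessionHeader(
            session_id=sid,
            patient_id=pid,
            check_in_time=datetime.fromisoformat(t_in),
            check_out_time=datetime.fromisoformat(t_out),
        )
    except ValueError as exc:
        if isinstance(exc, SessionParseError):
            raise
        raise SessionParseError(f"{xml_path}: bad timestamp ({exc})") from exc

    reports: list[ReportRecord] = []
    for elem in root.findall("REPORT"):
        service_id, report_time = _require(elem.attrib, _REPORT_ATTRS, xml_path)
        desc_elem = elem.find("DESCRIPTION")
        if desc_elem is None:
            raise SessionParseError(f"{xml_path}: REPORT missing DESCRIPTION element")
        try:
            parsed_time = datetime.fromisoformat(report_time)
        except ValueError as exc:
            raise SessionParseError(f"{xml_path}: bad timestamp ({exc})") from exc
        reports.append(
            ReportRecord(
                session=header,
                service_id=service_id,
                report_time=parsed_time,
                description=desc_elem.text or "",
            )
        )
    return header, reports


def parse_sessions_dir(directory: str | Path) -> list[tuple[SessionHeader, list[ReportRecord]]]:
    """Parse every ``*.xml`` file in a directory, in sorted filename order."""
    return [parse_session(p) for p in sorted(Path(directory).glob("*.xml"))]


def filter_cxr_reports(
    reports: Sequence[ReportRecord], cxr_service_id: str
) -> list[ReportRecord]:
    """Keep only reports whose SERVICE_ID equals the CXR service code.

    Exact string equality, order preserved, idempotent.
    """
    if not cxr_service_id:
        raise ValueError("cxr_service_id must be non-empty")
    return [r for r in reports if r.service_id == cxr_service_id]


def reports_to_frame(reports: Iterable[ReportRecord]) -> pd.DataFrame:
    """Flatten reports (with session header columns) to a table."""
    return pd.DataFrame(
        [
            {
                "session_id": r.session.session_id,
                "patient_id": r.session.patient_id,
                "check_in_time": r.session.check_in_time.isoformat(),
                "check_out_time": r.session.check_out_time.isoformat(),
                "service_id": r.service_id,
                "report_time": r.report_time.isoformat(),
                "description": r.description,
            }
            for r in reports
        ],
        columns=[
            "session_id",
            "patient_id",
            "check_in_time",
            "check_out_time",
            "service_id",
            "report_time",
            "description",
        ],
    )


def frame_to_reports(frame: pd.DataFrame) -> list[ReportRecord]:
    headers: dict[str, SessionHeader] = {}
    reports = []
    for row in frame.itertuples(index=False):
        sid = str(row.session_id)
        if sid not in headers:
            headers[sid] = SessionHeader(
                session_id=sid,
                patient_id=str(row.patient_id),
                check_in_time=datetime.fromisoformat(str(row.check_in_time)),
                check_out_time=datetime.fromisoformat(str(row.check_out_time)),
            )
        desc = row.description
        reports.append(
            ReportRecord(
                session=headers[sid],
                service_id=str(row.service_id),
                report_time=datetime.fromisoformat(str(row.report_time)),
                description="" if pd.isna(desc) else str(desc),
            )
        )
    return reports
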