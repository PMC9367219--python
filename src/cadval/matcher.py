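"""Record linkage between AI results and radiology reports.

PACS and HIS share no accession number at the study level, so linkage rests
on three conditions:

1. the AI result and the report belong to the same PATIENT_ID;
2. the STUDY_TIME falls inside the session window
   [CHECK_IN_TIME, CHECK_OUT_TIME] (inclusive);
3. the REPORT_TIME is within 24 hours of the STUDY_TIME.

By hospital protocol a report follows its study, so the default reading of
condition 3 is one-sided: 0 <= report_time - study_time <= 24 h
(``window_mode='forward'``); ``window_mode='absolute'`` accepts
|report_time - study_time| <= 24 h instead.

Among eligible candidates, assignment is one-to-one and greedy by smallest
report delay (ties broken lexicographically by study_uid, then session_id),
which is deterministic for a fixed input.  :func:`brute_force_match`
enumerates the eligible set without assignment and serves as the test oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import timedelta
from typing import Sequence

from .his_extract import ReportRecord
from .ingest import AIResult

logger = logging.getLogger(__name__)

MATCH_WINDOW = timedelta(hours=24)


@dataclass(frozen=True)
class MatchedPair:
    ai: AIResult
    report: ReportRecord
    report_delay: timedelta


@dataclass
class MatchOutcome:
    pairs: list[MatchedPair]
    unmatched_ai: list[AIResult]
    unmatched_reports: list[ReportRecord]
    n_ambiguous_groups: int = field(default=0)


def _eligible(ai: AIResult, report: ReportRecord, window_mode: str) -> bool:
    if ai.patient_id != report.session.patient_id:
        return False
    if not (report.session.check_in_time <= ai.study_time <= report.session.check_out_time):
        return False
    delay = report.report_time - ai.study_time
    if window_mode == "forward":
        return timedelta(0) <= delay <= MATCH_WINDOW
    if window_mode == "absolute":
        return abs(delay) <= MATCH_WINDOW
    raise ValueError(f"unknown window_mode {window_mode!r}")


def brute_force_match(
    ai_results: Sequence[AIResult],
    reports: Sequence[ReportRecord],
    window_mode: str = "forward",
) -> set[tuple[AIResult, ReportRecord]]:
    """Exhaustively enumerate all (AI result, report) pairs satisfying the
    three match conditions.  No assignment is performed; intended for small
    inputs and as an independent oracle for :func:`match_records`."""
    return {
        (ai, report)
        for ai in ai_results
        for report in reports
        if _eligible(ai, report, window_mode)
    }


def match_records(
    ai_results: Sequence[AIResult],
    reports: Sequence[ReportRecord],
    window_mode: str = "forward",
) -> MatchOutcome:
    """Link AI results to reports one-to-one under the three match conditions.

    Candidate pairs are ranked by report delay (absolute value under
    ``window_mode='absolute'``) and assigned greedily, so each AI result gets
    its nearest-in-time eligible report.  Every input record lands either in
    a pair or in the corresponding unmatched list.
    """
    by_patient: dict[str, list[int]] = {}
    for j, report in enumerate(reports):
        by_patient.setdefault(report.session.patient_id, []).append(j)

    candidates: list[tuple[timedelta, str, str, int, int]] = []
    per_ai: dict[int, int] = {}
    per_report: dict[int, int] = {}
    for i, ai in enumerate(ai_results):
        for j in by_patient.get(ai.patient_id, ()):
            report = reports[j]
            if _eligible(ai, report, window_mode):
                delay = report.report_time - ai.study_time
                candidates.append(
                    (abs(delay), ai.study_uid, report.session.session_id, i, j)
                )
                per_ai[i] = per_ai.get(i, 0) + 1
                per_report[j] = per_report.get(j, 0) + 1

    n_ambiguous = sum(1 for n in per_ai.values() if n > 1) + sum(
        1 for n in per_report.values() if n > 1
    )
    if n_ambiguous:
        logger.info("matching: %d records with multiple eligible candidates", n_ambiguous)

    candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3], c[4]))
    used_ai: set[int] = set()
    used_report: set[int] = set()
    pairs: list[MatchedPair] = []
    for _, _, _, i, j in candidates:
        if i in used_ai or j in used_report:
            continue
        used_ai.add(i)
        used_report.add(j)
        pairs.append(
            MatchedPair(
                ai=ai_results[i],
                report=reports[j],
                report_delay=reports[j].report_time - ai_results[i].study_time,
            )
        )

    unmatched_ai = [ai for i, ai in enumerate(ai_results) if i not in used_ai]
    unmatched_reports = [r for j, r in enumerate(reports) if j not in used_report]
    return MatchOutcome(
        pairs=pairs,
        unmatched_ai=unmatched_ai,
        unmatched_reports=unmatched_reports,
        n_ambiguous_groups=n_ambiguous,
    )


def match_log(outcome: MatchOutcome) -> dict:
    """Structured summary of a matching run (for the JSON run log)."""
    return {
        "n_pairs": len(outcome.pairs),
        "n_unmatched_ai": len(outcome.unmatched_ai),
        "n_unmatched_reports": len(outcome.unmatched_reports),
        "n_ambiguous_groups": outcome.n_ambiguous_groups,
    }
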