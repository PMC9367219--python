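"""End-to-end orchestration: ingest -> extract -> match -> label -> evaluate.

Mirrors the deployed validation flow: read study metadata, keep chest
radiographs, attach AI predictions, parse HIS session files, keep CXR
reports, link the two record sets by patient ID and time windows, derive
the ground-truth label of each matched report by template matching, and
estimate diagnostic performance with a percentile bootstrap.  Stage counts
(studies read, CXRs kept, reports kept, pairs matched) are recorded in the
summary for auditability.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import evaluation, his_extract, ingest, matcher
from .labeler import TemplateSet, label_report

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    studies: Path
    predictions: Path
    sessions: Path
    out_dir: Path
    cxr_service_id: str
    dialect: str = "table"  # or "dicom"
    templates: Path | None = None
    window_mode: str = "forward"
    n_boot: int = 10_000
    seed: int = 0
    extra: dict = field(default_factory=dict)


def _metric_value(v: float | None) -> float | None:
    return None if v is None else float(v)


def evaluate_pairs(
    pairs: list[evaluation.LabeledPair], n_boot: int, seed: int
) -> dict:
    """Confusion counts, point metrics, and bootstrap summary as a plain dict."""
    cm = evaluation.confusion(pairs)
    ms = evaluation.metrics(cm)
    bs = evaluation.bootstrap_f1(pairs, n_boot=n_boot, seed=seed)
    return {
        "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
        "metrics": {
            "accuracy": _metric_value(ms.accuracy),
            "sensitivity": _metric_value(ms.sensitivity),
            "specificity": _metric_value(ms.specificity),
            "precision": _metric_value(ms.precision),
            "f1": _metric_value(ms.f1),
        },
        "bootstrap": {
            "n_boot": bs.n_boot,
            "seed": bs.seed,
            "mean_f1": bs.mean_f1,
            "ci_low": bs.ci_low,
            "ci_high": bs.ci_high,
            "n_degenerate": bs.n_degenerate,
        },
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write per-stage tables plus a metrics JSON.

    Returns the summary dict (also written to ``out_dir/metrics.json``).
    Any stage failure propagates with the stage name prefixed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    name = stage("ingest")
    try:
        studies = ingest.load_studies(config.studies, dialect=config.dialect)
        counts["studies_read"] = len(studies)
        predictions = pd.read_csv(config.predictions)
        ai_results = ingest.attach_predictions(studies, predictions)
        counts["cxr_ai_results"] = len(ai_results)

        name = stage("extract")
        sessions = his_extract.parse_sessions_dir(config.sessions)
        counts["sessions_read"] = len(sessions)
        all_reports = [r for _, reports in sessions for r in reports]
        cxr_reports = his_extract.filter_cxr_reports(
            all_reports, config.cxr_service_id
        )
        counts["reports_read"] = len(all_reports)
        counts["cxr_reports"] = len(cxr_reports)

        name = stage("match")
        outcome = matcher.match_records(
            ai_results, cxr_reports, window_mode=config.window_mode
        )
        counts["pairs_matched"] = len(outcome.pairs)

        name = stage("label")
        template_set = (
            TemplateSet.load(config.templates)
            if config.templates
            else TemplateSet.default()
        )
        pairs = [
            evaluation.LabeledPair(
                study_uid=p.ai.study_uid,
                truth=label_report(p.report.description, template_set).label,
                prediction=p.ai.abnormal_status,
            )
            for p in outcome.pairs
        ]
        counts["labels_assigned"] = len(pairs)

        name = stage("evaluate")
        summary = {
            "counts": counts,
            "match_log": matcher.match_log(outcome),
            **evaluate_pairs(pairs, n_boot=config.n_boot, seed=config.seed),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    ingest.ai_results_to_frame(ai_results).to_csv(
        out_dir / "ai_results.csv", index=False
    )
    his_extract.reports_to_frame(cxr_reports).to_csv(
        out_dir / "cxr_reports.csv", index=False
    )
    pairs_frame = pd.DataFrame(
        [
            {"study_uid": p.study_uid, "truth": p.truth, "prediction": p.prediction}
            for p in pairs
        ],
        columns=["study_uid", "truth", "prediction"],
    )
    pairs_frame.to_csv(out_dir / "pairs.csv", index=False)
    (out_dir / "metrics.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return summary


def make_fixture_from_paper() -> list[evaluation.LabeledPair]:
    """Rebuild the published 6,285-study evaluation set from its marginals.

    The reference deployment reported 1,756 abnormal and 4,529 normal
    matched studies with sensitivity 68.6% and specificity 83.9%; nearest-
    integer reconstruction of the confusion matrix expanded to labeled
    pairs reproduces every published point metric.
    """
    cm = evaluation.reconstruct_from_summary(1756, 4529, 0.686, 0.839)
    return evaluation.expand_cm_to_pairs(cm)
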