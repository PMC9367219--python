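"""Synthetic hospital corpus: determinism, marginals, and truth recovery."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from cadval.evaluation import LabeledPair, confusion, metrics
from cadval.his_extract import filter_cxr_reports
from cadval.ingest import attach_predictions
from cadval.labeler import TemplateSet, label_report
from cadval.matcher import match_records
from cadval.synthetic import (
    ConfigurationError,
    GeneratorConfig,
    generate_corpus,
    write_corpus,
)


def run_downstream(corpus):
    """Ingest -> match -> label on an in-memory corpus; returns labeled pairs."""
    preds = pd.DataFrame(
        {
            "study_uid": [p.study_uid for p in corpus.predictions],
            "abnormal_status": [p.abnormal_status for p in corpus.predictions],
        }
    )
    ai = attach_predictions(corpus.studies, preds)
    reports = filter_cxr_reports(
        [r for _, rs in corpus.sessions for r in rs], corpus.config.cxr_service_id
    )
    outcome = match_records(ai, reports)
    templates = TemplateSet.default()
    return [
        LabeledPair(
            study_uid=p.ai.study_uid,
            truth=label_report(p.report.description, templates).label,
            prediction=p.ai.abnormal_status,
        )
        for p in outcome.pairs
    ]


def tree_digest(directory: Path) -> str:
    digest = hashlib.sha256()
    for path in sorted(directory.rglob("*")):
        if path.is_file():
            digest.update(str(path.relative_to(directory)).encode())
            digest.update(path.read_bytes())
    return digest.hexdigest()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"prevalence": 1.2},
            {"sensitivity": -0.1},
            {"unmatched_report_rate": 2.0},
            {"n_patients": 0},
            {"studies_per_patient_mean": 0.5},
            {"report_delay_max_hours": 30.0},
            {"cxr_service_id": ""},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(**kwargs)


class TestDeterminism:
    def test_same_seed_byte_identical_corpus(self, tmp_path):
        config = GeneratorConfig(n_patients=80, seed=3)
        dirs = []
        for name in ("a", "b"):
            corpus = generate_corpus(config)
            write_corpus(corpus, tmp_path / name)
            dirs.append(tmp_path / name)
        assert tree_digest(dirs[0]) == tree_digest(dirs[1])

    def test_different_seed_differs(self, tmp_path):
        for seed, name in ((3, "a"), (4, "b")):
            corpus = generate_corpus(GeneratorConfig(n_patients=80, seed=seed))
            write_corpus(corpus, tmp_path / name)
        assert tree_digest(tmp_path / "a") != tree_digest(tmp_path / "b")


class TestMarginals:
    def test_zero_prevalence_means_no_abnormal_truth(self):
        corpus = generate_corpus(GeneratorConfig(n_patients=200, prevalence=0.0, seed=1))
        assert corpus.truth["truth"].sum() == 0

    def test_prevalence_within_binomial_tolerance(self, small_corpus):
        n = len(small_corpus.truth)
        p = small_corpus.config.prevalence
        se = np.sqrt(p * (1 - p) / n)
        assert abs(small_corpus.truth["truth"].mean() - p) < 3 * se

    def test_sensitivity_specificity_recovered_at_deployment_scale(self):
        """Generated predictions vs hidden truth reproduce the configured
        operating point within 3 binomial standard errors at n ~ 6,285."""
        config = GeneratorConfig(seed=17)  # deployment-scale defaults
        corpus = generate_corpus(config)
        merged = corpus.truth.merge(
            pd.DataFrame(
                {
                    "study_uid": [p.study_uid for p in corpus.predictions],
                    "prediction": [p.abnormal_status for p in corpus.predictions],
                }
            ),
            on="study_uid",
        )
        pos = merged[merged.truth == 1]
        neg = merged[merged.truth == 0]
        sens_hat = pos.prediction.mean()
        spec_hat = 1 - neg.prediction.mean()
        se_sens = np.sqrt(config.sensitivity * (1 - config.sensitivity) / len(pos))
        se_spec = np.sqrt(config.specificity * (1 - config.specificity) / len(neg))
        assert abs(sens_hat - config.sensitivity) < 3 * se_sens
        assert abs(spec_hat - config.specificity) < 3 * se_spec


class TestCorpusInvariants:
    def test_unique_study_uids(self, small_corpus):
        uids = [s.study_uid for s in small_corpus.studies]
        assert len(uids) == len(set(uids))

    def test_truth_covers_every_study(self, small_corpus):
        assert set(small_corpus.truth.study_uid) == {
            s.study_uid for s in small_corpus.studies
        }

    def test_every_expected_match_has_exactly_one_eligible_report(self, small_corpus):
        from cadval.matcher import brute_force_match

        preds = {p.study_uid: p for p in small_corpus.predictions}
        reports = filter_cxr_reports(
            [r for _, rs in small_corpus.sessions for r in rs],
            small_corpus.config.cxr_service_id,
        )
        expected = set(
            small_corpus.truth.loc[small_corpus.truth.expect_match, "study_uid"]
        )
        sample = [preds[uid] for uid in sorted(expected)][:120]
        eligible = brute_force_match(sample, reports)
        counts = {ai.study_uid: 0 for ai in sample}
        for ai, _report in eligible:
            counts[ai.study_uid] += 1
        assert all(c == 1 for c in counts.values())


class TestEndToEnd:
    def test_clean_corpus_recovers_truth_exactly(self, clean_corpus):
        pairs = run_downstream(clean_corpus)
        truth = clean_corpus.truth.set_index("study_uid")
        assert len(pairs) == len(truth)
        for pair in pairs:
            assert pair.truth == truth.loc[pair.study_uid, "truth"]

    def test_perfect_classifier_yields_perfect_metrics(self):
        config = GeneratorConfig(
            n_patients=250,
            sensitivity=1.0,
            specificity=1.0,
            unmatched_report_rate=0.0,
            unmatched_study_rate=0.0,
            nuisance_modality_rate=0.0,
            out_of_window_rate=0.0,
            seed=31,
        )
        pairs = run_downstream(generate_corpus(config))
        ms = metrics(confusion(pairs))
        assert ms.f1 == 1.0
        assert ms.accuracy == 1.0

    def test_noisy_corpus_recovers_operating_point(self, small_corpus):
        pairs = run_downstream(small_corpus)
        cm = confusion(pairs)
        ms = metrics(cm)
        config = small_corpus.config
        n_pos, n_neg = cm.tp + cm.fn, cm.tn + cm.fp
        se_sens = np.sqrt(config.sensitivity * (1 - config.sensitivity) / n_pos)
        se_spec = np.sqrt(config.specificity * (1 - config.specificity) / n_neg)
        assert abs(ms.sensitivity - config.sensitivity) < 3 * se_sens
        assert abs(ms.specificity - config.specificity) < 3 * se_spec
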