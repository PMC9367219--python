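"""Diagnostic-performance estimation for a binary abnormality classifier.

With "abnormal" as the positive class, the confusion matrix over matched
(truth, prediction) pairs yields accuracy, sensitivity (recall),
specificity, precision, and the F1 score

    F1 = TP / (TP + (FP + FN) / 2),

the harmonic mean of precision and recall.  Uncertainty is quantified by a
percentile bootstrap: resample the matched pairs with replacement (default
10,000 replicates), compute F1 per replicate, and take the mean and the
empirical 2.5th / 97.5th percentiles (linear interpolation) as the point
summary and 95% confidence interval.

Replicates whose F1 denominator is zero (no positive calls and no positive
truths) are excluded from the mean and percentiles and counted in
``n_degenerate``; at any realistic prevalence this is unreachable.

:func:`reconstruct_from_summary` rebuilds integer confusion counts from
published class sizes and sensitivity/specificity by nearest-integer
rounding, so a published evaluation can be reproduced without the
underlying (non-shareable) clinical records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class LabeledPair:
    """One matched study: report-derived truth vs AI prediction (1=abnormal)."""

    study_uid: str
    truth: int
    prediction: int

    def __post_init__(self) -> None:
        if self.truth not in (0, 1) or self.prediction not in (0, 1):
            raise ValueError("truth and prediction must be 0 or 1")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """Point metrics; a field is None when its denominator is zero."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None


@dataclass(frozen=True)
class BootstrapResult:
    n_boot: int
    seed: int
    mean_f1: float
    ci_low: float
    ci_high: float
    n_degenerate: int
    samples: np.ndarray | None = None


def confusion(pairs: Sequence[LabeledPair]) -> ConfusionMatrix:
    """Tally the 2x2 confusion matrix over labeled pairs."""
    if not pairs:
        raise ValueError("cannot build a confusion matrix from zero pairs")
    tp = sum(1 for p in pairs if p.truth == 1 and p.prediction == 1)
    fp = sum(1 for p in pairs if p.truth == 0 and p.prediction == 1)
    fn = sum(1 for p in pairs if p.truth == 1 and p.prediction == 0)
    tn = sum(1 for p in pairs if p.truth == 0 and p.prediction == 0)
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def f1_score(cm: ConfusionMatrix) -> float:
    """F1 = TP / (TP + (FP+FN)/2); NaN when the denominator is zero."""
    denom = cm.tp + (cm.fp + cm.fn) / 2
    if denom == 0:
        return math.nan
    return cm.tp / denom


def _ratio(num: int, denom: int) -> float | None:
    return None if denom == 0 else num / denom


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """All point metrics from a confusion matrix; None flags an undefined
    (zero-denominator) metric, never a silent zero."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    f1 = f1_score(cm)
    return MetricSet(
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        precision=_ratio(cm.tp, cm.tp + cm.fp),
        f1=None if math.isnan(f1) else f1,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def reconstruct_from_summary(
    n_pos: int, n_neg: int, sensitivity: float, specificity: float
) -> ConfusionMatrix:
    """Rebuild integer confusion counts from published marginals.

    tp = round(sensitivity * n_pos), tn = round(specificity * n_neg), with
    nearest-integer rounding (half away from zero); fn and fp are the
    complements within each class.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("class sizes must be nonnegative")
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("rates must be in [0, 1]")
    tp = _round_half_away(sensitivity * n_pos)
    tn = _round_half_away(specificity * n_neg)
    return ConfusionMatrix(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)


def expand_cm_to_pairs(cm: ConfusionMatrix) -> list[LabeledPair]:
    """Materialize a confusion matrix as labeled pairs with synthetic uids."""
    pairs: list[LabeledPair] = []
    for kind, (truth, pred), count in (
        ("tp", (1, 1), cm.tp),
        ("fp", (0, 1), cm.fp),
        ("fn", (1, 0), cm.fn),
        ("tn", (0, 0), cm.tn),
    ):
        pairs.extend(
            LabeledPair(study_uid=f"{kind}-{k:05d}", truth=truth, prediction=pred)
            for k in range(count)
        )
    return pairs


def bootstrap_f1(
    pairs: Sequence[LabeledPair],
    n_boot: int = 10_000,
    seed: int = 0,
    keep_samples: bool = False,
) -> BootstrapResult:
    """Percentile bootstrap of the F1 score.

    Each replicate draws ``len(pairs)`` pairs with replacement and computes
    F1; the summary is the mean over defined replicates and the empirical
    2.5th/97.5th percentiles (numpy linear interpolation).  Deterministic
    for a fixed seed.
    """
    if not pairs:
        raise ValueError("cannot bootstrap zero pairs")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    # category code per pair: 0=TP 1=FP 2=FN 3=TN
    codes = np.array(
        [0 if (p.truth, p.prediction) == (1, 1)
         else 1 if (p.truth, p.prediction) == (0, 1)
         else 2 if (p.truth, p.prediction) == (1, 0)
         else 3 for p in pairs],
        dtype=np.int8,
    )
    n = len(codes)
    rng = np.random.default_rng(seed)
    f1s = np.empty(n_boot, dtype=np.float64)
    chunk = max(1, min(n_boot, int(2e7) // n))
    start = 0
    while start < n_boot:
        stop = min(start + chunk, n_boot)
        idx = rng.integers(0, n, size=(stop - start, n))
        drawn = codes[idx]
        tp = (drawn == 0).sum(axis=1)
        fp = (drawn == 1).sum(axis=1)
        fn = (drawn == 2).sum(axis=1)
        denom = tp + (fp + fn) / 2
        with np.errstate(invalid="ignore", divide="ignore"):
            f1s[start:stop] = np.where(denom > 0, tp / denom, np.nan)
        start = stop

    valid = f1s[~np.isnan(f1s)]
    n_degenerate = n_boot - valid.size
    if valid.size == 0:
        raise ValueError("all bootstrap replicates had an undefined F1")
    ci_low, ci_high = np.percentile(valid, [2.5, 97.5])
    return BootstrapResult(
        n_boot=n_boot,
        seed=seed,
        mean_f1=float(valid.mean()),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_degenerate=int(n_degenerate),
        samples=f1s if keep_samples else None,
    )
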