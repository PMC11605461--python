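"""Metrics, confidence intervals, model comparison and sensitivity analyses.

Conventions: scores are probabilities in [0, 1]; labels are 0/1 with 1 = lung
cancer; the decision rule at a threshold t is ``score >= t``. The default
operating point is 0.4, chosen so the positive predictive value clears the
NICE 3% fast-track referral convention. AUROC is the Mann-Whitney statistic
(ties counted 1/2); confidence intervals are patient-level nonparametric
percentile bootstraps; correlated AUROCs are compared with DeLong's test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.40, 0.701, 0.05), 2))


def confusion_at_threshold(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) under the rule ``score >= threshold``."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size == 0:
        raise ValueError("empty input")
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return tp, fp, tn, fn


def ppv(tp: int, fp: int) -> float:
    """Positive predictive value TP/(TP+FP); NaN when undefined."""
    return tp / (tp + fp) if tp + fp > 0 else math.nan


def sensitivity(tp: int, fn: int) -> float:
    """Sensitivity (recall) TP/(TP+FN); NaN when undefined."""
    return tp / (tp + fn) if tp + fn > 0 else math.nan


def specificity(tn: int, fp: int) -> float:
    return tn / (tn + fp) if tn + fp > 0 else math.nan


def npv(tn: int, fn: int) -> float:
    return tn / (tn + fn) if tn + fn > 0 else math.nan


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; NaN if either is undefined."""
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        return math.nan
    return 2 * precision * recall / (precision + recall)


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUROC with ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class MetricsReport:
    """Per-class precision/recall/F1 plus specificity, NPV and AUROC."""

    threshold: float
    auroc: float
    precision_pos: float
    recall_pos: float
    f1_pos: float
    precision_neg: float
    recall_neg: float
    f1_neg: float
    specificity: float
    npv: float
    n: int
    n_positive: int
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "auroc": self.auroc,
            "precision_pos": self.precision_pos,
            "recall_pos": self.recall_pos,
            "f1_pos": self.f1_pos,
            "precision_neg": self.precision_neg,
            "recall_neg": self.recall_neg,
            "f1_neg": self.f1_neg,
            "specificity": self.specificity,
            "npv": self.npv,
            "n": self.n,
            "n_positive": self.n_positive,
            "ci": {k: list(v) for k, v in self.ci.items()},
        }


def metrics_report(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.4,
    n_boot: int = 0,
    seed: int = 0,
) -> MetricsReport:
    """Compute the full metric panel at an operating point.

    With ``n_boot`` > 0, 95% percentile-bootstrap CIs are attached for the
    positive-class precision/recall and AUROC.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    tp, fp, tn, fn = confusion_at_threshold(s, y, threshold)
    prec_p, rec_p = ppv(tp, fp), sensitivity(tp, fn)
    prec_n, rec_n = npv(tn, fn), specificity(tn, fp)
    report = MetricsReport(
        threshold=threshold,
        auroc=auroc(s, y),
        precision_pos=prec_p,
        recall_pos=rec_p,
        f1_pos=f1(prec_p, rec_p),
        precision_neg=prec_n,
        recall_neg=rec_n,
        f1_neg=f1(prec_n, rec_n),
        specificity=rec_n,
        npv=prec_n,
        n=int(y.size),
        n_positive=int(y.sum()),
    )
    if n_boot:
        report.ci["auroc"] = bootstrap_ci(s, y, auroc, n_boot=n_boot, seed=seed)
        report.ci["precision_pos"] = bootstrap_ci(
            s, y, lambda a, b: ppv(*confusion_at_threshold(a, b, threshold)[:2]),
            n_boot=n_boot, seed=seed,
        )
        report.ci["recall_pos"] = bootstrap_ci(
            s, y,
            lambda a, b: sensitivity(
                confusion_at_threshold(a, b, threshold)[0],
                confusion_at_threshold(a, b, threshold)[3],
            ),
            n_boot=n_boot, seed=seed,
        )
    return report


def bootstrap_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    metric: Callable[[np.ndarray, np.ndarray], float],
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Patient-level nonparametric percentile bootstrap interval.

    Resamples in which the metric is undefined (single class, NaN) are redrawn
    and logged.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = s.size
    if n < 20:
        raise ValueError("bootstrap needs n >= 20")
    rng = np.random.default_rng(seed)
    values = np.empty(n_boot)
    redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                v = metric(s[idx], y[idx])
            except ValueError:
                v = math.nan
            if math.isnan(v):
                redrawn += 1
                continue
            values[b] = v
            break
    if redrawn:
        logger.info("bootstrap_ci: redrew %d degenerate resamples", redrawn)
    alpha = (1.0 - level) / 2
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components (V10, V01) and the AUROC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    # pairwise psi via broadcasting: 1 if pos>neg, 0.5 if tie
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    theta = cmp.mean()
    v10 = cmp.mean(axis=1)  # per positive
    v01 = cmp.mean(axis=0)  # per negative
    return v10, v01, float(theta)


def delong_compare(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[int]
) -> tuple[float, float]:
    """DeLong test for two correlated AUROCs on paired predictions.

    Returns (AUROC_A - AUROC_B, two-sided p-value).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("paired scores must have equal length")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes must be present")
    v10_a, v01_a, th_a = _delong_components(a, y)
    v10_b, v01_b, th_b = _delong_components(b, y)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = th_a - th_b
    if var <= 0:
        return float(diff), 1.0 if diff == 0 else 0.0
    z = diff / math.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(diff), float(p)


def delong_variance(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[int]
) -> float:
    """Variance estimate of (AUROC_A - AUROC_B) from DeLong's components."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    v10_a, v01_a, _ = _delong_components(a, y)
    v10_b, v01_b, _ = _delong_components(b, y)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    return float(
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / v10_a.size
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / v01_a.size
    )


@dataclass(frozen=True)
class ThresholdRow:
    threshold: float
    n_predicted_positive: int
    n_true_positive: int
    n_positives: int
    sensitivity: float
    ppv: float


def threshold_sweep(
    scores: Sequence[float],
    labels: Sequence[int],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> list[ThresholdRow]:
    """One row per threshold, mirroring an operating-point comparison table."""
    rows = []
    for t in thresholds:
        tp, fp, tn, fn = confusion_at_threshold(scores, labels, t)
        rows.append(
            ThresholdRow(
                threshold=float(t),
                n_predicted_positive=tp + fp,
                n_true_positive=tp,
                n_positives=tp + fn,
                sensitivity=sensitivity(tp, fn),
                ppv=ppv(tp, fp),
            )
        )
    return rows


@dataclass
class GridCell:
    lookback_months: int
    trim_months: int
    report: MetricsReport | None
    flagged: str | None = None  # reason if the cell could not be evaluated
    selected: bool = False


def sensitivity_grid(
    evaluate_cell: Callable[[int, int], tuple[Sequence[float], Sequence[int]]],
    lookbacks: Sequence[int] = (12, 24, 36),
    trims: Sequence[int] = (0, 1, 3),
    threshold: float = 0.4,
    min_cases: int = 10,
    selected_cell: tuple[int, int] = (36, 1),
) -> list[GridCell]:
    """Trimming × lookback sensitivity grid.

    ``evaluate_cell(lookback, trim)`` must re-derive pathways for that window,
    retrain, and return (scores, labels) on the held-out set; this function
    assembles the 9-cell grid of metric reports. The conservative operating
    window — full 36-month lookback less the immediate month — is marked as
    the selected configuration.
    """
    cells = []
    for lb in lookbacks:
        for tr in trims:
            scores, labels = evaluate_cell(lb, tr)
            labels_arr = np.asarray(labels)
            flagged = None
            report = None
            if labels_arr.sum() < min_cases:
                flagged = f"only {int(labels_arr.sum())} cases (< {min_cases})"
            else:
                report = metrics_report(scores, labels_arr, threshold=threshold)
            cells.append(
                GridCell(
                    lookback_months=lb,
                    trim_months=tr,
                    report=report,
                    flagged=flagged,
                    selected=(lb, tr) == tuple(selected_cell),
                )
            )
    return cells


def subgroup_report(
    scores: Sequence[float],
    labels: Sequence[int],
    attributes: Mapping[str, Sequence],
    threshold: float = 0.4,
    min_group_size: int = 50,
) -> dict[str, dict[str, dict]]:
    """Descriptive metric panels per demographic group (e.g. sex, ethnicity).

    Groups smaller than ``min_group_size`` (or single-class) are flagged
    rather than reported. No multiplicity adjustment is applied.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    out: dict[str, dict[str, dict]] = {}
    for attr, values in attributes.items():
        v = np.asarray(values)
        if v.shape != y.shape:
            raise ValueError(f"attribute {attr!r} length mismatch")
        out[attr] = {}
        for g in sorted(set(v.tolist())):
            mask = v == g
            entry: dict = {"n": int(mask.sum())}
            if mask.sum() < min_group_size:
                entry["flagged"] = "group below minimum size"
            elif len(set(y[mask].tolist())) < 2:
                entry["flagged"] = "single-class group"
            else:
                entry["report"] = metrics_report(s[mask], y[mask], threshold=threshold)
            out[attr][str(g)] = entry
    return out
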