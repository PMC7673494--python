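"""Model validation: rank AUC with a Hanley-McNeil significance test,
TSS maximization, and threshold-dependent confusion metrics.

Two identities hold on every report and are asserted wherever a report
is built: ``TSS = sensitivity + specificity - 1`` at the reported
threshold, and ``misclassification = 1 - correct classification``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "EvaluationReport",
    "auc_rank",
    "auc_test",
    "tss_curve",
    "max_tss_threshold",
    "confusion_metrics",
    "evaluate_scores",
]


def auc_rank(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Mann-Whitney AUC with midranks for ties.

    ``AUC = (R_pos - n_p (n_p + 1) / 2) / (n_p n_a)`` where ``R_pos`` is
    the rank sum of the positive scores in the pooled ranking.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def auc_test(auc: float, n_p: int, n_a: int) -> tuple[float, tuple[float, float], float]:
    """Hanley-McNeil standard error, 95% CI and two-tailed p vs AUC 0.5.

    SE uses ``Q1 = A/(2-A)`` and ``Q2 = 2A^2/(1+A)`` evaluated at the
    observed AUC (the convention recorded in the report); the null test
    statistic is ``z = (A - 0.5)/SE`` with ``p = 2(1 - Phi(|z|))``; the
    CI is ``A +/- 1.96 SE`` clipped to [0, 1].
    """
    if n_p < 1 or n_a < 1:
        raise ValueError("need at least one observation per class")
    a = float(auc)
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n_p - 1) * (q1 - a * a) + (n_a - 1) * (q2 - a * a)) / (
        n_p * n_a
    )
    se = math.sqrt(max(var, 0.0))
    if se == 0.0:
        # degenerate A in {0, 1} at tiny n: p below machine floor
        return 0.0, (a, a), 0.0 if a != 0.5 else 1.0
    z = (a - 0.5) / se
    p = 2 * (1 - norm.cdf(abs(z)))
    ci = (max(0.0, a - 1.96 * se), min(1.0, a + 1.96 * se))
    return se, ci, float(p)


def tss_curve(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Sensitivity/specificity/TSS swept over all candidate thresholds.

    Thresholds are the sorted unique score values plus 0 and 1; a site
    is predicted present when ``score > threshold`` (strict).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    thresholds = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    rows = []
    pos = labels == 1
    neg = ~pos
    for th in thresholds:
        pred = scores > th
        se = (pred & pos).sum() / pos.sum()
        sp = (~pred & neg).sum() / neg.sum()
        rows.append(
            {"threshold": th, "sensitivity": se, "specificity": sp, "tss": se + sp - 1}
        )
    return pd.DataFrame(rows)


def max_tss_threshold(curve: pd.DataFrame) -> float:
    """Threshold maximizing TSS; ties resolve to the smallest threshold."""
    best = curve["tss"].max()
    return float(curve.loc[curve["tss"] >= best - 1e-12, "threshold"].min())


def confusion_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> dict[str, float]:
    """Threshold-dependent metrics from the 2x2 table at ``score > threshold``:
    Cohen's kappa, sensitivity, specificity, correct and misclassification."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels == 1
    neg = ~pos
    if pos.sum() == 0 or neg.sum() == 0:
        raise ValueError("both classes must be present")
    pred = scores > threshold
    tp = int((pred & pos).sum())
    fn = int((~pred & pos).sum())
    fp = int((pred & neg).sum())
    tn = int((~pred & neg).sum())
    n = tp + fn + fp + tn
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else 0.0
    return {
        "kappa": kappa,
        "sensitivity": se,
        "specificity": sp,
        "correct_classification": p_o,
        "misclassification": 1 - p_o,
    }


@dataclass
class EvaluationReport:
    """One model's threshold-independent + threshold-dependent metrics."""

    model: str
    auc: float
    auc_se: float
    auc_ci_low: float
    auc_ci_high: float
    p_two_tailed: float
    tss_max: float
    threshold: float
    kappa: float
    sensitivity: float
    specificity: float
    correct_classification: float
    misclassification: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.auc <= 1.0
        assert self.auc_ci_low - 1e-12 <= self.auc <= self.auc_ci_high + 1e-12
        assert abs(self.tss_max - (self.sensitivity + self.specificity - 1)) < 1e-9
        assert abs(self.misclassification - (1 - self.correct_classification)) < 1e-9

    def as_row(self) -> dict:
        return asdict(self)


def evaluate_scores(
    model_name: str, scores: np.ndarray, labels: np.ndarray
) -> EvaluationReport:
    """Full report for one model's scores against 0/1 labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    auc = auc_rank(pos, neg)
    se, ci, p = auc_test(auc, pos.size, neg.size)
    curve = tss_curve(scores, labels)
    th = max_tss_threshold(curve)
    cm = confusion_metrics(scores, labels, th)
    return EvaluationReport(
        model=model_name,
        auc=auc,
        auc_se=se,
        auc_ci_low=ci[0],
        auc_ci_high=ci[1],
        p_two_tailed=p,
        tss_max=cm["sensitivity"] + cm["specificity"] - 1,
        threshold=th,
        **cm,
    )
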