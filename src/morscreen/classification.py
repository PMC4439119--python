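"""Discriminant analysis of marker combinations and per-marker ROC/AUC.

A linear discriminant with priors proportional to the group sizes is fit on
a complete (substituted) marker table; the primary reported metric is the
resubstitution confusion matrix with per-group and overall accuracies,
optionally leave-one-out cross-validated instead.  Each marker additionally
gets a two-group AUC computed by the rank (concordance) statistic
U / (n1·n2) with tied pairs counted 0.5, oriented so AUC >= 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_curve

from .data_model import NumericalError, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    auc: float
    orientation: str       # "case_high" or "case_low"
    degenerate: bool       # all scores identical
    curve: pd.DataFrame    # fpr, tpr, threshold (for the oriented scores)


def roc_auc(scores: np.ndarray, is_case: np.ndarray) -> RocResult:
    """Concordance AUC of one marker, ties counted as half.

    AUC = P(score_case > score_control) + 0.5 P(tie), computed from
    mid-ranks; the orientation (whether cases score high or low) is chosen
    so the reported AUC is >= 0.5 and recorded in the result.
    """
    scores = np.asarray(scores, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    if np.isnan(scores).any():
        raise ValidationError("scores contain missing values")
    n1 = int((~is_case).sum())
    n2 = int(is_case.sum())
    if n1 < 1 or n2 < 1:
        raise ValidationError("need >= 1 sample per group")
    ranks = stats.rankdata(scores)
    u = ranks[is_case].sum() - n2 * (n2 + 1) / 2.0
    auc = u / (n1 * n2)
    degenerate = bool(np.all(scores == scores[0]))
    if auc >= 0.5:
        orientation, oriented = "case_high", scores
    else:
        orientation, oriented = "case_low", -scores
        auc = 1.0 - auc
    fpr, tpr, thr = roc_curve(is_case.astype(int), oriented)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return RocResult(float(auc), orientation, degenerate, curve)


# ---------------------------------------------------------------------------
# Linear discriminant analysis
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    markers: list[str]
    confusion: pd.DataFrame         # rows = true group, cols = predicted
    accuracy_control: float         # percent
    accuracy_case: float            # percent
    accuracy_overall: float         # percent
    mode: str                       # "resubstitution" or "loo"
    priors: str
    marker_auc: pd.Series           # per-marker concordance AUC


def lda_classify(features: pd.DataFrame, group: pd.Series,
                 control_label: str = "control", case_label: str = "case",
                 priors: str = "proportional",
                 mode: str = "resubstitution") -> ClassificationReport:
    """Fit a linear discriminant on a complete marker table and score it.

    Parameters
    ----------
    features
        samples x markers table without missing values.
    priors
        ``"proportional"`` (to group sizes) or ``"equal"``.
    mode
        ``"resubstitution"`` scores the training data itself (the primary
        metric); ``"loo"`` refits with each sample left out in turn.
    """
    if features.isna().to_numpy().any():
        raise ValidationError("features contain missing values; substitute first")
    if mode not in ("resubstitution", "loo"):
        raise ValidationError(f"unknown mode {mode!r}")
    group = group.reindex(features.index)
    y = (group == case_label).to_numpy(dtype=int)
    n1, n2 = int((y == 0).sum()), int((y == 1).sum())
    if n1 < 2 or n2 < 2:
        raise ValidationError("need >= 2 samples per group")
    X = features.to_numpy(dtype=float)
    pooled = ((n1 - 1) * np.cov(X[y == 0], rowvar=False, ddof=1)
              + (n2 - 1) * np.cov(X[y == 1], rowvar=False, ddof=1)) / (n1 + n2 - 2)
    pooled = np.atleast_2d(pooled)
    if np.linalg.matrix_rank(pooled) < X.shape[1]:
        raise NumericalError(
            "singular pooled covariance; use fewer or less collinear markers")
    prior_vec = None if priors == "proportional" else [0.5, 0.5]

    def fit_predict(train_idx: np.ndarray, test_idx: np.ndarray) -> np.ndarray:
        clf = LinearDiscriminantAnalysis(priors=prior_vec)
        try:
            clf.fit(X[train_idx], y[train_idx])
        except np.linalg.LinAlgError as exc:
            raise NumericalError(
                "singular pooled covariance; use fewer or less collinear "
                "markers") from exc
        return clf.predict(X[test_idx])

    all_idx = np.arange(len(y))
    if mode == "resubstitution":
        pred = fit_predict(all_idx, all_idx)
    else:
        pred = np.empty(len(y), dtype=int)
        for i in all_idx:
            pred[i] = fit_predict(np.delete(all_idx, i), np.array([i]))[0]

    labels = [control_label, case_label]
    confusion = pd.DataFrame(0, index=labels, columns=labels)
    for true, hat in zip(y, pred):
        confusion.iloc[true, hat] += 1
    acc_c = 100.0 * confusion.iloc[0, 0] / n1
    acc_a = 100.0 * confusion.iloc[1, 1] / n2
    acc = 100.0 * (confusion.iloc[0, 0] + confusion.iloc[1, 1]) / (n1 + n2)

    marker_auc = pd.Series(
        {m: roc_auc(features[m].to_numpy(), y.astype(bool)).auc
         for m in features.columns})
    report = ClassificationReport(list(features.columns), confusion,
                                  float(acc_c), float(acc_a), float(acc),
                                  mode, priors, marker_auc)
    logger.info("LDA (%s): %.1f%% control / %.1f%% case / %.1f%% overall",
                mode, acc_c, acc_a, acc)
    return report
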