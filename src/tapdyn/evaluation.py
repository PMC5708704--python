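"""Evaluation: train/test splitting, k-fold CV, confusion metrics, ROC/AUC,
and Welch's one-way ANOVA on predicted probabilities.

Two evaluation modes are provided.  A single stratified 0.65:0.35 train/test
split mirrors a simple hold-out protocol, but at cohort sizes of a few dozen
subjects the test half is small, so stratified 10-fold cross-validation —
with the entire preprocessing chain (imputation, scaling, LDA) refit inside
each training fold to avoid leakage — is the default for headline metrics.
Per-fold metrics are reported alongside the pooled confusion matrix built
from each subject's single out-of-fold prediction.

Sensitivity, specificity and accuracy are reported on the 0-100 scale:

    sensitivity = TP / (TP + FN) * 100
    specificity = (1 - FP / (FP + TN)) * 100
    accuracy    = (TP + TN) / total * 100

Displayed values round to the nearest integer; full precision is retained
internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .ensemble import EnsembleConfig, fit_ensemble, predict, predictions_to_frame
from .features import FEATURE_NAMES

__all__ = [
    "ConfusionMatrix",
    "Metrics",
    "EvaluationReport",
    "CVResult",
    "WelchAnovaResult",
    "compute_metrics",
    "display_percent",
    "split_train_test",
    "kfold_cv",
    "roc_auc",
    "welch_anova",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @staticmethod
    def from_predictions(y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionMatrix":
        t = np.asarray(y_true, dtype=int)
        p = np.asarray(y_pred, dtype=int)
        return ConfusionMatrix(
            tp=int(np.sum((t == 1) & (p == 1))),
            tn=int(np.sum((t == 0) & (p == 0))),
            fp=int(np.sum((t == 0) & (p == 1))),
            fn=int(np.sum((t == 1) & (p == 0))),
        )


@dataclass(frozen=True)
class Metrics:
    """Percentages on the 0-100 scale; NaN marks an undefined denominator."""

    sensitivity: float
    specificity: float
    accuracy: float


def compute_metrics(cm: ConfusionMatrix) -> Metrics:
    """Sensitivity, specificity and accuracy (percent) from a confusion matrix.

    A metric whose denominator is zero is NaN, never silently 0.
    """
    if cm.total == 0:
        raise ValueError("cannot compute metrics from an empty confusion matrix")
    sens = cm.tp / (cm.tp + cm.fn) * 100 if (cm.tp + cm.fn) > 0 else math.nan
    spec = (1 - cm.fp / (cm.fp + cm.tn)) * 100 if (cm.fp + cm.tn) > 0 else math.nan
    acc = (cm.tp + cm.tn) / cm.total * 100
    return Metrics(sensitivity=sens, specificity=spec, accuracy=acc)


def display_percent(x: float) -> Optional[int]:
    """Round a percentage for display (half away from zero); None if NaN."""
    if math.isnan(x):
        return None
    return int(math.floor(x + 0.5))


def split_train_test(
    X: pd.DataFrame,
    y: Sequence[int],
    ratio: float = 0.65,
    seed: int = 0,
):
    """Stratified, reproducible train/test split (``ratio`` = training share)."""
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    y = np.asarray(y, dtype=int)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=ratio, stratify=y, random_state=seed
    )
    return X_tr, X_te, y_tr, y_te


@dataclass
class EvaluationReport:
    confusion: ConfusionMatrix
    metrics: Metrics
    auc: float
    n: int
    roc_points: Optional[pd.DataFrame] = None
    welch: Optional["WelchAnovaResult"] = None

    def to_dict(self) -> dict:
        d = {
            "tp": self.confusion.tp,
            "tn": self.confusion.tn,
            "fp": self.confusion.fp,
            "fn": self.confusion.fn,
            "sensitivity": self.metrics.sensitivity,
            "specificity": self.metrics.specificity,
            "accuracy": self.metrics.accuracy,
            "auc": self.auc,
            "n": self.n,
        }
        if self.welch is not None:
            d.update(
                welch_f=self.welch.f, welch_df1=self.welch.df1,
                welch_df2=self.welch.df2, welch_p=self.welch.p,
            )
        return d


@dataclass
class CVResult:
    pooled: EvaluationReport
    fold_reports: list
    predictions: pd.DataFrame  # one out-of-fold row per subject
    mean_fold_metrics: Metrics
    k: int


def _report_from_predictions(
    y_true: np.ndarray, p: np.ndarray, labels: np.ndarray, with_roc: bool = True
) -> EvaluationReport:
    cm = ConfusionMatrix.from_predictions(y_true, labels)
    auc, points = roc_auc(p, y_true)
    return EvaluationReport(
        confusion=cm,
        metrics=compute_metrics(cm),
        auc=auc,
        n=len(y_true),
        roc_points=points if with_roc else None,
    )


def evaluate_split(
    X: pd.DataFrame,
    y: Sequence[int],
    ratio: float = 0.65,
    config: Optional[EnsembleConfig] = None,
    seed: int = 0,
) -> EvaluationReport:
    """Hold-out evaluation: fit on the training share, score the test share."""
    config = config or EnsembleConfig(seed=seed)
    X_tr, X_te, y_tr, y_te = split_train_test(X, y, ratio=ratio, seed=seed)
    model = fit_ensemble(X_tr, y_tr, config)
    results = predict(model, X_te)
    p = np.array([r.p_pd for r in results])
    lab = np.array([int(r.label) for r in results])
    return _report_from_predictions(np.asarray(y_te), p, lab)


def kfold_cv(
    X: pd.DataFrame,
    y: Sequence[int],
    k: int = 10,
    config: Optional[EnsembleConfig] = None,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation of the full pipeline.

    Every subject lands in exactly one validation fold; preprocessing and all
    sixteen base models are refit from scratch on each training fold.  Fold
    metrics are averaged into a single estimate, and a pooled report is built
    from the out-of-fold predictions.  ``k`` is reduced (with a warning) if it
    exceeds the size of the smaller class.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    config = config or EnsembleConfig(seed=seed)
    y = np.asarray(y, dtype=int)
    min_class = int(np.bincount(y).min())
    if k > min_class:
        warnings.warn(
            f"k={k} exceeds the smaller class size {min_class}; reducing k",
            stacklevel=2,
        )
        k = min_class
        if k < 2:
            raise ValueError("smaller class has fewer than 2 subjects; cannot cross-validate")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_reports = []
    pred_rows = []
    for fold, (tr_idx, va_idx) in enumerate(skf.split(X, y)):
        model = fit_ensemble(X.iloc[tr_idx], y[tr_idx], config)
        results = predict(model, X.iloc[va_idx])
        frame = predictions_to_frame(results)
        frame["fold"] = fold
        frame["y_true"] = y[va_idx]
        pred_rows.append(frame)
        p = frame["p_pd"].to_numpy()
        lab = frame["label"].to_numpy()
        fold_reports.append(
            _report_from_predictions(y[va_idx], p, lab, with_roc=False)
        )

    predictions = pd.concat(pred_rows)
    pooled = _report_from_predictions(
        predictions["y_true"].to_numpy(),
        predictions["p_pd"].to_numpy(),
        predictions["label"].to_numpy(),
    )
    g_pd = predictions.loc[predictions["label"] == 1, "p_pd"].to_numpy()
    g_ct = predictions.loc[predictions["label"] == 0, "p_pd"].to_numpy()
    if g_pd.size >= 2 and g_ct.size >= 2:
        pooled.welch = welch_anova(g_pd, g_ct)
    mean_fold = Metrics(
        sensitivity=float(np.nanmean([r.metrics.sensitivity for r in fold_reports])),
        specificity=float(np.nanmean([r.metrics.specificity for r in fold_reports])),
        accuracy=float(np.nanmean([r.metrics.accuracy for r in fold_reports])),
    )
    return CVResult(
        pooled=pooled,
        fold_reports=fold_reports,
        predictions=predictions,
        mean_fold_metrics=mean_fold,
        k=k,
    )


def roc_auc(probabilities: Sequence[float], labels: Sequence[int]):
    """AUC and ROC points; AUC is NaN when only one class is present.

    The rank-based AUC equals the probability that a random positive subject
    outranks a random negative one, counting ties as one half.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        return math.nan, None
    auc = float(roc_auc_score(y, p))
    fpr, tpr, thr = roc_curve(y, p)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return auc, points


@dataclass(frozen=True)
class WelchAnovaResult:
    f: float
    df1: float
    df2: float
    p: float


def welch_anova(*groups: Sequence[float]) -> WelchAnovaResult:
    """Welch's heteroscedastic one-way ANOVA.

    Does not assume equal group variances; degrees of freedom follow the
    Welch-Satterthwaite approximation.  For two groups the F statistic equals
    the square of Welch's t.  Returns NaN statistics when every group has
    zero variance (the test is undefined).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    k = len(gs)
    if k < 2 or any(g.size < 2 for g in gs):
        raise ValueError("welch_anova needs at least 2 groups with at least 2 values each")
    n = np.array([g.size for g in gs], dtype=float)
    m = np.array([g.mean() for g in gs])
    v = np.array([g.var(ddof=1) for g in gs])
    if np.any(v == 0):
        # a zero-variance group gives that group infinite weight; the
        # statistic is undefined (covers the all-degenerate case too)
        return WelchAnovaResult(math.nan, k - 1.0, math.nan, math.nan)
    w = n / v
    sw = w.sum()
    grand = (w * m).sum() / sw
    a = (w * (m - grand) ** 2).sum() / (k - 1)
    tail = ((1 - w / sw) ** 2 / (n - 1)).sum()
    b = 1 + 2 * (k - 2) / (k**2 - 1) * tail
    f = float(a / b)
    df1 = float(k - 1)
    df2 = float((k**2 - 1) / (3 * tail))
    p = float(stats.f.sf(f, df1, df2))
    return WelchAnovaResult(f=f, df1=df1, df2=df2, p=p)
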