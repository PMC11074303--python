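"""Evaluation battery: pooled t-test on PC1, per-region ROC/AUC with
optimal segmentation thresholds, per-class confusion metrics, and
learning curves.

Conventions follow the tissue-classification literature this pipeline
targets: the separation between cancerous and non-cancerous pixels is
screened by a pooled two-sample Student t-test on the first principal
component; segmentation quality per tissue region (fat / muscle /
cancer) is the one-vs-rest AUC of the classifier's class probability,
with the operating threshold chosen to maximize Youden's J = sensitivity
+ specificity - 1 (ties broken toward higher sensitivity, since missing
cancer is the costlier error); per-class confusion counts are denoted
mu (TP), mu1 (TN), Gamma (FP), Gamma1 (FN).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .errors import DimensionError, UndefinedAUCError

__all__ = [
    "TTestResult",
    "ConfusionMatrix",
    "ClassificationReport",
    "LearningCurves",
    "EvalReport",
    "two_sample_ttest",
    "auc",
    "best_threshold",
    "classification_report",
    "learning_curves",
]


@dataclass
class TTestResult:
    """Pooled two-sample t-test summary for mean(a) - mean(b)."""

    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    log10_p: float
    confidence_interval: tuple[float, float]
    pooled_sd: float
    mean_difference: float

    def to_dict(self) -> dict:
        return {
            "t_statistic": self.t_statistic,
            "degrees_of_freedom": self.degrees_of_freedom,
            "p_value": self.p_value,
            "log10_p": self.log10_p,
            "confidence_interval": list(self.confidence_interval),
            "pooled_sd": self.pooled_sd,
            "mean_difference": self.mean_difference,
        }


def two_sample_ttest(a: np.ndarray, b: np.ndarray) -> TTestResult:
    """Pooled-variance Student t-test with a 95% CI for the mean difference.

    df = n1 + n2 - 2.  ``log10_p`` is computed from the t log-survival
    function so extreme significance survives double underflow.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need at least 2 observations")
    df = n1 + n2 - 2
    diff = float(a.mean() - b.mean())
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if pooled_var == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0, 0.0, (0.0, 0.0), 0.0, 0.0)
        raise ZeroDivisionError("zero pooled variance with unequal means: t undefined")
    sp = math.sqrt(pooled_var)
    se = sp * math.sqrt(1.0 / n1 + 1.0 / n2)
    t = diff / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    log10_p = float((math.log(2.0) + stats.t.logsf(abs(t), df)) / math.log(10.0))
    half = float(stats.t.ppf(0.975, df) * se)
    return TTestResult(float(t), df, p, log10_p, (diff - half, diff + half), float(sp), diff)


def auc(scores: np.ndarray, positives: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with half-credit for ties.

    Equals the trapezoidal area under the empirical ROC curve and the
    probability that a random positive outscores a random negative.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    positives = np.asarray(positives).astype(bool).ravel()
    if scores.shape != positives.shape:
        raise DimensionError("scores and positives must have the same length")
    if positives.all() or not positives.any():
        raise UndefinedAUCError("AUC undefined: need both positive and negative pixels")
    return float(roc_auc_score(positives, scores))


def best_threshold(scores: np.ndarray, positives: np.ndarray) -> tuple[float, float, float]:
    """Operating threshold maximizing Youden's J; predict positive iff score >= t.

    Ties in J are broken toward higher sensitivity (lower threshold):
    missing a cancerous pixel is the costlier error.
    Returns (threshold, sensitivity, specificity).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    positives = np.asarray(positives).astype(bool).ravel()
    if positives.all() or not positives.any():
        raise UndefinedAUCError("threshold undefined: need both classes")
    n_pos, n_neg = positives.sum(), (~positives).sum()

    best = (-np.inf, -np.inf, np.nan, np.nan, np.nan)  # (J, sens, thr, sens, spec)
    candidates = np.concatenate([np.unique(scores), [np.inf]])
    for thr in candidates:
        pred = scores >= thr
        sens = float((pred & positives).sum() / n_pos)
        spec = float((~pred & ~positives).sum() / n_neg)
        j = sens + spec - 1.0
        if (j, sens) > best[:2]:
            best = (j, sens, float(thr), sens, spec)
    return best[2], best[3], best[4]


@dataclass
class ConfusionMatrix:
    """Per-class one-vs-rest counts: mu=TP, mu1=TN, gamma=FP, gamma1=FN."""

    classes: list
    counts: dict  # class -> {"mu": int, "mu1": int, "gamma": int, "gamma1": int}

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray, classes=None) -> "ConfusionMatrix":
        y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise DimensionError("y_true and y_pred must have the same length")
        if classes is None:
            classes = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
        counts = {}
        for c in classes:
            tp = int(((y_true == c) & (y_pred == c)).sum())
            tn = int(((y_true != c) & (y_pred != c)).sum())
            fp = int(((y_true != c) & (y_pred == c)).sum())
            fn = int(((y_true == c) & (y_pred != c)).sum())
            counts[c] = {"mu": tp, "mu1": tn, "gamma": fp, "gamma1": fn}
        return cls(list(classes), counts)


@dataclass
class ClassificationReport:
    """Per-class accuracy/precision/recall/F1 plus the raw confusion counts."""

    per_class: pd.DataFrame
    confusion: ConfusionMatrix
    overall_accuracy: float


def _safe_div(num: float, den: float, what: str):
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); reported as NaN", stacklevel=3)
        return float("nan")
    return num / den


def classification_report(y_true: np.ndarray, y_pred: np.ndarray, classes=None) -> ClassificationReport:
    """One-vs-rest metrics per class.

    accuracy = (mu + mu1)/N, precision = mu/(mu + Gamma),
    recall = mu/(mu + Gamma1), F1 = 2PR/(P+R).  Undefined ratios (empty
    denominator) surface as NaN with a warning rather than silent zeros.
    """
    cm = ConfusionMatrix.from_predictions(y_true, y_pred, classes)
    n = len(np.asarray(y_true))
    rows = []
    for c in cm.classes:
        k = cm.counts[c]
        precision = _safe_div(k["mu"], k["mu"] + k["gamma"], f"precision[{c}]")
        recall = _safe_div(k["mu"], k["mu"] + k["gamma1"], f"recall[{c}]")
        if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
            warnings.warn(f"F1[{c}] undefined; reported as NaN", stacklevel=2)
            f1 = float("nan")
        else:
            f1 = 2 * precision * recall / (precision + recall)
        rows.append(
            {
                "class": c,
                "accuracy": (k["mu"] + k["mu1"]) / n,
                "precision": precision,
                "recall": recall,
                "f1": f1,
            }
        )
    overall = float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))
    return ClassificationReport(pd.DataFrame(rows).set_index("class"), cm, overall)


@dataclass
class LearningCurves:
    """Epoch-indexed train/validation loss and accuracy with summary flags."""

    table: pd.DataFrame
    best_val_epoch: int | None
    plateau: bool


def learning_curves(round_log: list[dict], plateau_delta: float = 1e-4, plateau_window: int = 10) -> LearningCurves:
    """Condense a round log into per-epoch curves.

    Reports the epoch with the highest validation accuracy (the model
    state one would keep) and flags a plateau when the monitored metric
    fails to improve by more than ``plateau_delta`` over the final
    ``plateau_window`` epochs.
    """
    if not round_log:
        raise ValueError("round log is empty")
    df = pd.DataFrame(round_log)
    cols = [c for c in ("full_loss", "loss", "train_acc", "val_loss", "val_acc") if c in df.columns]
    table = df.groupby("round")[cols].mean()
    table.index.name = "epoch"

    best_val_epoch = None
    if "val_acc" in table.columns:
        best_val_epoch = int(table["val_acc"].idxmax())

    if "val_acc" in table.columns:
        monitored = table["val_acc"].to_numpy()
    else:
        loss_col = "full_loss" if "full_loss" in table.columns else "loss"
        monitored = -table[loss_col].to_numpy()
    plateau = False
    if monitored.size > plateau_window:
        tail, prior = monitored[-plateau_window:], monitored[: -plateau_window]
        plateau = bool(tail.max() - prior.max() <= plateau_delta)
    return LearningCurves(table, best_val_epoch, plateau)


@dataclass
class EvalReport:
    """Everything the pipeline reports about one trained model."""

    metrics: ClassificationReport
    region_auc: dict
    region_thresholds: dict
    ttest: TTestResult | None
    curves: LearningCurves | None
    privacy: dict | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "overall_accuracy": self.metrics.overall_accuracy,
            "per_class": json.loads(self.metrics.per_class.to_json(orient="index")),
            "confusion": {str(c): self.metrics.confusion.counts[c] for c in self.metrics.confusion.classes},
            "region_auc": {str(k): v for k, v in self.region_auc.items()},
            "region_thresholds": {
                str(k): {"threshold": t[0], "sensitivity": t[1], "specificity": t[2]}
                for k, t in self.region_thresholds.items()
            },
        }
        if self.ttest is not None:
            d["pc1_ttest"] = self.ttest.to_dict()
        if self.curves is not None:
            d["best_val_epoch"] = self.curves.best_val_epoch
            d["plateau"] = self.curves.plateau
        if self.privacy is not None:
            d["privacy"] = {k: v for k, v in self.privacy.items() if k != "bytes_per_round"}
        d.update(self.extras)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)
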