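"""Classification metrics for multi-class motor-imagery decoding.

From a confusion matrix (rows = true class, columns = predicted class)
this module derives overall accuracy, Cohen's kappa, per-class
precision/recall/F1 with macro averages, and per-subject summary
statistics (mean and sample standard deviation), i.e. the full metric
suite conventionally reported for within-subject BCI benchmarks.

Cohen's kappa is the chance-corrected agreement

    kappa = (Po - Pe) / (1 - Pe)

with ``Po`` the observed accuracy and ``Pe`` the chance agreement.  By
default ``Pe`` is computed from the confusion-matrix marginals,
``Pe = sum_k row_k * col_k / C^2``; ``pe_mode="uniform"`` instead fixes
``Pe = 1/n_classes`` (the value the marginal form takes for a balanced
test set scored by a balanced predictor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "confusion_matrix",
    "one_vs_rest_counts",
    "metrics_from_cm",
    "aggregate_subjects",
    "EvalReport",
    "SubjectSummary",
    "subject_table",
]


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Count matrix with cell ``(i, j) = #{true i, predicted j}``."""
    y_true = np.asarray(y_true, dtype=np.int64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.int64).ravel()
    if y_true.shape != y_pred.shape:
        raise ValidationError(f"length mismatch: {y_true.shape[0]} true vs {y_pred.shape[0]} predicted")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValidationError(f"{name}: labels must lie in [0, {n_classes})")
    cm = np.bincount(y_true * n_classes + y_pred, minlength=n_classes * n_classes)
    return cm.reshape(n_classes, n_classes)


def one_vs_rest_counts(cm: np.ndarray, k: int) -> tuple[int, int, int, int]:
    """``(TP, TN, FP, FN)`` for class ``k`` against the rest.

    ``TP + TN + FP + FN`` always equals the matrix total.
    """
    cm = np.asarray(cm)
    c = int(cm.sum())
    tp = int(cm[k, k])
    fp = int(cm[:, k].sum()) - tp
    fn = int(cm[k, :].sum()) - tp
    tn = c - tp - fp - fn
    return tp, tn, fp, fn


@dataclass
class EvalReport:
    """Confusion matrix and the metrics derived from it.

    Per-class arrays are indexed by class; ``macro_*`` are unweighted
    class means (macro-F1 averages the per-class F1 values, it is not the
    harmonic mean of the macro precision/recall).
    """

    cm: np.ndarray
    accuracy: float
    kappa: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    pe: float
    class_names: list[str] | None = None

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    def cm_frame(self) -> pd.DataFrame:
        """Confusion matrix as a labeled table (rows true, columns predicted)."""
        names = self.class_names or [f"class{i}" for i in range(len(self.precision))]
        return pd.DataFrame(self.cm, index=pd.Index(names, name="true"),
                            columns=pd.Index(names, name="predicted"))

    def to_frame(self) -> pd.DataFrame:
        """Per-class metric table (rows = classes, plus a macro-average row)."""
        names = self.class_names or [f"class{i}" for i in range(len(self.precision))]
        df = pd.DataFrame(
            {"precision": self.precision, "recall": self.recall, "f1": self.f1},
            index=pd.Index(names, name="class"),
        )
        df.loc["macro_avg"] = [self.macro_precision, self.macro_recall, self.macro_f1]
        return df


def metrics_from_cm(
    cm: np.ndarray,
    pe_mode: str = "marginals",
    class_names: list[str] | None = None,
) -> EvalReport:
    """Accuracy, Cohen's kappa and per-class precision/recall/F1.

    Accuracy is ``trace / C``.  Classes with an empty precision or recall
    denominator score 0 (with a warning).  ``Pe = 1`` (total marginal
    agreement) yields ``kappa = 0`` by convention.
    """
    cm = np.asarray(cm, dtype=np.float64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValidationError(f"confusion matrix must be square, got {cm.shape}")
    if (cm < 0).any():
        raise ValidationError("confusion matrix cells must be non-negative")
    c = cm.sum()
    if c == 0:
        raise ValidationError("confusion matrix total is 0; nothing was scored")
    n_classes = cm.shape[0]

    po = np.trace(cm) / c
    row = cm.sum(axis=1)  # TP + FN per class
    col = cm.sum(axis=0)  # TP + FP per class
    if pe_mode == "marginals":
        pe = float((row * col).sum() / c**2)
    elif pe_mode == "uniform":
        pe = 1.0 / n_classes
    else:
        raise ValidationError(f"pe_mode must be 'marginals' or 'uniform', got {pe_mode!r}")
    if pe == 1.0:
        warnings.warn("Pe = 1 (total marginal agreement); kappa defined as 0", stacklevel=2)
        kappa = 0.0
    else:
        kappa = (po - pe) / (1.0 - pe)

    tp = np.diag(cm)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, tp / np.where(col > 0, col, 1), 0.0)
        recall = np.where(row > 0, tp / np.where(row > 0, row, 1), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
    if (col == 0).any() or (row == 0).any():
        warnings.warn("class with empty precision/recall denominator scored as 0", stacklevel=2)

    return EvalReport(
        cm=cm.astype(np.int64) if np.allclose(cm, np.round(cm)) else cm,
        accuracy=float(po),
        kappa=float(kappa),
        precision=precision,
        recall=recall,
        f1=f1,
        pe=pe,
        class_names=class_names,
    )


@dataclass
class SubjectSummary:
    """Per-subject metric values with their mean and sample (n-1) SD."""

    values: np.ndarray
    mean: float
    sd: float | None


def aggregate_subjects(values) -> SubjectSummary:
    """Arithmetic mean and sample standard deviation across subjects.

    The SD uses the ``n - 1`` denominator, the convention that reproduces
    published per-subject summary rows; it requires at least two values.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 1:
        raise ValidationError("aggregate_subjects requires at least one value")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size >= 2 else None
    return SubjectSummary(values=values, mean=mean, sd=sd)


def subject_table(reports: dict[str, EvalReport]) -> pd.DataFrame:
    """One row per subject: accuracy, kappa, per-class precision/recall, F1.

    Suitable for CSV export; a ``mean``/``sd`` pair of summary rows is
    appended when there are at least two subjects.
    """
    rows = {}
    for subject, rep in reports.items():
        names = rep.class_names or [f"class{i}" for i in range(len(rep.precision))]
        row: dict[str, float] = {"accuracy": rep.accuracy, "kappa": rep.kappa}
        for i, name in enumerate(names):
            row[f"precision_{name}"] = rep.precision[i]
            row[f"recall_{name}"] = rep.recall[i]
        row["macro_f1"] = rep.macro_f1
        rows[subject] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject"
    if len(df) >= 2:
        summary = pd.DataFrame(
            {col: [df[col].mean(), df[col].std(ddof=1)] for col in df.columns},
            index=pd.Index(["mean", "sd"], name="subject"),
        )
        df = pd.concat([df, summary])
    return df
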