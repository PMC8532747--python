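"""Train/test splitting, confusion matrices and agreement metrics.

Metrics follow the usual multiclass conventions: accuracy is the diagonal
fraction (the binary TP+TN form generalizes to trace/total), class precision
is TP over the row (predicted) total, class recall is TP over the column
(true) total, and Cohen's kappa corrects the observed agreement for the
agreement expected from the row/column marginals alone.  A model is accepted
when kappa exceeds 0.60.

Precision or recall of a class that was never predicted (or never occurs) is
undefined; it is reported as 0 with an explicit flag rather than raising,
matching how such cells are conventionally printed.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .quality import CLASS_LABELS, N_CLASSES, QualityClass

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "split_train_test",
    "confusion_matrix",
    "accuracy",
    "class_precision",
    "class_recall",
    "cohens_kappa",
    "evaluation_report",
    "round_half_up",
    "load_reference_confusion",
]

#: Kappa threshold above which a model is accepted.
DEFAULT_KAPPA_THRESHOLD = 0.60


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (printed-table style)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ConfusionMatrix:
    """4x4 count matrix indexed ``counts[predicted, true]`` in class order."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"counts must be {N_CLASSES}x{N_CLASSES}, got {c.shape}")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if c.sum() == 0:
            raise ValueError("confusion matrix must contain at least one observation")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def predicted_totals(self) -> np.ndarray:  # row sums
        return self.counts.sum(axis=1)

    @property
    def true_totals(self) -> np.ndarray:  # column sums
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(CLASS_LABELS), columns=list(CLASS_LABELS))

    def pretty(self) -> str:
        """Printed layout: predicted rows x true columns, with class metrics."""
        df = self.to_frame().copy()
        df["Class precision (%)"] = [
            round_half_up(class_precision(self, c)) for c in QualityClass
        ]
        recall_row = {
            lbl: round_half_up(class_recall(self, c))
            for lbl, c in zip(CLASS_LABELS, QualityClass)
        }
        recall_row["Class precision (%)"] = "-"
        df.loc["Class recall (%)"] = recall_row
        return df.to_string()


def confusion_matrix(truth: Sequence, pred: Sequence) -> ConfusionMatrix:
    """Build ``counts[p, t] = #{i : pred_i = p and truth_i = t}``."""
    t = _to_codes(truth)
    p = _to_codes(pred)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} truth vs {len(p)} predicted labels")
    if len(t) == 0:
        raise ValueError("need at least one observation")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (p, t), 1)
    return ConfusionMatrix(counts)


def _to_codes(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "iu":
        return arr.astype(np.int64)
    return np.array(
        [QualityClass.from_label(l) if isinstance(l, str) else int(l) for l in arr],
        dtype=np.int64,
    )


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall agreement, percent: 100 x trace / total."""
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def class_precision(cm: ConfusionMatrix, cls: QualityClass) -> float:
    """Percent of predictions of ``cls`` that are correct; 0 if never predicted."""
    row = cm.predicted_totals[cls]
    if row == 0:
        return 0.0
    return 100.0 * float(cm.counts[cls, cls]) / float(row)


def class_recall(cm: ConfusionMatrix, cls: QualityClass) -> float:
    """Percent of true ``cls`` observations predicted as such; 0 if class absent."""
    col = cm.true_totals[cls]
    if col == 0:
        return 0.0
    return 100.0 * float(cm.counts[cls, cls]) / float(col)


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement; NaN when chance agreement is exactly 1."""
    n = cm.total
    p_o = float(np.trace(cm.counts)) / n
    p_e = float(cm.predicted_totals @ cm.true_totals) / (n * n)
    if p_e == 1.0:
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class EvalReport:
    """All evaluation metrics plus the kappa acceptance verdict."""

    cm: ConfusionMatrix
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    kappa: float
    kappa_threshold: float
    accepted: bool
    undefined_precision: dict[str, bool] = field(default_factory=dict)
    undefined_recall: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": self.cm.counts.tolist(),
            "class_order": list(CLASS_LABELS),
            "accuracy_pct": self.accuracy,
            "precision_pct": self.precision,
            "recall_pct": self.recall,
            "kappa": None if math.isnan(self.kappa) else self.kappa,
            "kappa_threshold": self.kappa_threshold,
            "accepted": self.accepted,
            "undefined_precision": self.undefined_precision,
            "undefined_recall": self.undefined_recall,
        }

    def summary(self) -> str:
        lines = [
            "Rearing-condition model evaluation",
            "=" * 50,
            self.cm.pretty(),
            "",
            f"Accuracy: {self.accuracy:.2f}%",
            f"Cohen's kappa: {self.kappa:.4f}"
            + (f"  (> {self.kappa_threshold:.2f}: accepted)" if self.accepted
               else f"  (<= {self.kappa_threshold:.2f}: rejected)"),
        ]
        return "\n".join(lines)


def evaluation_report(
    cm: ConfusionMatrix, kappa_threshold: float = DEFAULT_KAPPA_THRESHOLD
) -> EvalReport:
    """Aggregate all metrics; ``accepted`` iff kappa exceeds the threshold."""
    kappa = cohens_kappa(cm)
    return EvalReport(
        cm=cm,
        accuracy=accuracy(cm),
        precision={c.label: class_precision(cm, c) for c in QualityClass},
        recall={c.label: class_recall(cm, c) for c in QualityClass},
        kappa=kappa,
        kappa_threshold=kappa_threshold,
        accepted=bool(not math.isnan(kappa) and kappa > kappa_threshold),
        undefined_precision={
            c.label: bool(cm.predicted_totals[c] == 0) for c in QualityClass
        },
        undefined_recall={c.label: bool(cm.true_totals[c] == 0) for c in QualityClass},
    )


def split_train_test(
    table: pd.DataFrame,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratify_by: str | None = "arcf",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded train/test split, stratified by the label where counts allow.

    Strata are allocated train slots by largest remainder, so the train size
    is within one row of ``round(train_fraction * n)``.  A stratum with a
    single member forces a plain unstratified split (with a warning).
    """
    n = len(table)
    if n < 5:
        raise ValueError(f"need at least 5 rows to split, got {n}")
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    df = table.reset_index(drop=True)

    strata: list[np.ndarray]
    if stratify_by is not None and stratify_by in df.columns:
        groups = [np.flatnonzero((df[stratify_by] == v).to_numpy())
                  for v in sorted(df[stratify_by].unique())]
        if any(len(g) < 2 for g in groups):
            warnings.warn(
                "a stratum has a single member; falling back to an unstratified split",
                stacklevel=2,
            )
            strata = [np.arange(n)]
        else:
            strata = groups
    else:
        strata = [np.arange(n)]

    target_train = round(train_fraction * n)
    quotas = np.array([train_fraction * len(g) for g in strata])
    takes = np.floor(quotas).astype(int)
    remainder_order = np.argsort(-(quotas - takes), kind="mergesort")
    for i in remainder_order:
        if takes.sum() >= target_train:
            break
        takes[i] += 1

    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for g, k in zip(strata, takes):
        perm = rng.permutation(g)
        train_idx.append(perm[:k])
        test_idx.append(perm[k:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    return df.iloc[tr].reset_index(drop=True), df.iloc[te].reset_index(drop=True)


def load_reference_confusion(which: str) -> dict:
    """Load a packaged reference confusion-matrix fixture.

    ``which`` is ``"random_tree"`` or ``"decision_tree"``.  The returned dict
    carries the counts, the metric values printed alongside the original
    matrix, and per-cell consistency flags (printed values that disagree with
    the matrix's own counts are flagged and should not be asserted equal).
    """
    name = f"reference_confusion_{which}.json"
    with resources.files("broilerenv.data").joinpath(name).open() as fh:
        doc = json.load(fh)
    doc["matrix"] = ConfusionMatrix(np.asarray(doc["counts"], dtype=np.int64))
    return doc
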