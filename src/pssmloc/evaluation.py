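"""Group-aware 10-fold cross-validation with per-location accuracies.

Overall accuracy Q = 100 * C / N (correct over total samples). Multi-location
proteins appear once per annotated location in the sample table; their
duplicated samples share identical feature rows, so the splitter keeps all
samples of a protein in the same fold to avoid train/test leakage. A paired
two-sided t-test utility is included for comparing matched accuracy vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

from .formats import SampleTable
from .rotation_forest import RotationForestConfig, fit as rf_fit, predict as rf_predict


@dataclass
class CVReport:
    """Held-out predictions and accuracy summaries from one CV run."""

    fold_assignments: np.ndarray
    predictions: np.ndarray
    truth: np.ndarray
    classes: list[str]
    overall_Q: float
    per_location_Q: dict[str, float | None]
    confusion: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "overall_Q": self.overall_Q,
            "per_location_Q": self.per_location_Q,
            "classes": list(self.classes),
            "fold_assignments": self.fold_assignments.tolist(),
            "predictions": self.predictions.tolist(),
            "truth": self.truth.tolist(),
            "confusion": self.confusion.to_dict(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_text(self) -> str:
        """Human-readable per-location table plus overall accuracy."""
        lines = ["Location accuracies (%)", "-" * 40]
        for label in self.classes:
            q = self.per_location_Q.get(label)
            shown = f"{q:6.1f}" if q is not None else "   n/a"
            lines.append(f"{label:<28s}{shown}")
        lines.append("-" * 40)
        lines.append(f"{'Overall Q':<28s}{self.overall_Q:6.1f}")
        return "\n".join(lines)


def kfold_split(samples: SampleTable, k: int = 10, seed: int = 0) -> np.ndarray:
    """Assign each sample to one of k folds, keeping protein groups intact.

    Groups (all samples sharing a protein id) are shuffled, then placed
    largest-first onto the currently smallest fold, which keeps fold sizes as
    even as the group structure allows (within 1 for all-singleton data).
    Pure function of (samples, k, seed).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    keys = samples.group_keys
    group_ids: dict[str, list[int]] = {}
    for idx, key in enumerate(keys):
        group_ids.setdefault(key, []).append(idx)
    groups = list(group_ids.values())
    if k > len(groups):
        raise ValueError(f"k={k} exceeds the number of protein groups ({len(groups)})")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    # stable sort keeps the shuffled order within each size class
    order = order[np.argsort([-len(groups[i]) for i in order], kind="stable")]

    fold_sizes = np.zeros(k, dtype=int)
    assignment = np.empty(len(samples), dtype=int)
    for gi in order:
        fold = int(np.argmin(fold_sizes))
        for idx in groups[gi]:
            assignment[idx] = fold
        fold_sizes[fold] += len(groups[gi])
    return assignment


def accuracy_Q(predictions: Sequence, truth: Sequence) -> float:
    """Overall accuracy Q = 100 * correct / total, in percent."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape or predictions.size == 0:
        raise ValueError("predictions and truth must be equal-length and non-empty")
    return 100.0 * float(np.mean(predictions == truth))


def per_location_accuracy(
    predictions: Sequence,
    truth: Sequence,
    labels: Sequence[str],
) -> dict[str, float | None]:
    """Accuracy restricted to each true location; empty locations map to None.

    Reporting absent classes as missing rather than 0 keeps genuinely
    misclassified small classes distinguishable from classes with no samples.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    out: dict[str, float | None] = {}
    for label in labels:
        mask = truth == label
        out[label] = accuracy_Q(predictions[mask], truth[mask]) if mask.any() else None
    return out


def cross_validate(
    samples: SampleTable,
    X: np.ndarray,
    cfg: RotationForestConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> CVReport:
    """k-fold CV of a Rotation Forest over a feature matrix aligned to samples.

    Per fold, the model is fitted on the other k-1 folds and its predictions
    on the held-out fold are recorded; the report pools all held-out
    predictions, so every sample is predicted exactly once.
    """
    cfg = cfg or RotationForestConfig()
    X = np.asarray(X, dtype=float)
    if X.shape[0] != len(samples):
        raise ValueError("feature matrix rows must align with the sample table")
    y = np.asarray(samples.labels)
    folds = kfold_split(samples, k=k, seed=seed)
    predictions = np.empty_like(y)
    for fold in range(k):
        test = folds == fold
        model = rf_fit(X[~test], y[~test], cfg)
        predictions[test] = rf_predict(model, X[test])

    classes = sorted(set(y))
    confusion = pd.DataFrame(
        _sk_confusion(y, predictions, labels=classes), index=classes, columns=classes
    )
    return CVReport(
        fold_assignments=folds,
        predictions=predictions,
        truth=y,
        classes=classes,
        overall_Q=accuracy_Q(predictions, y),
        per_location_Q=per_location_accuracy(predictions, y, classes),
        confusion=confusion,
    )


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided paired t-test p-value for matched accuracy vectors.

    Computes t = mean(d) / (sd(d)/sqrt(n)) on the differences d = a - b and
    the p-value from the t distribution with n-1 degrees of freedom. All-zero
    difference variance is a degenerate error (t undefined); a zero mean with
    positive variance gives t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired t-test needs two equal-length vectors of length >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("differences have zero variance; paired t is undefined")
    t = d.mean() / (sd / np.sqrt(d.size))
    return float(2.0 * stats.t.sf(abs(t), df=d.size - 1))
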