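"""Split protocol, 5-fold CV, and per-class one-vs-rest metrics.

Evaluation follows the protocol of training on five-sixths of each class
with the remaining sixth held out, plus stratified 5-fold CV in which
the *entire* pipeline -- feature selection and normalization included --
is refit on the training folds only.  Per-class metrics collapse the
5x5 confusion matrix to one-vs-rest counts:

    Acc = (TP + TN) / (TP + FN + FP + TN)
    Sp  = TN / (FP + TN)
    Sn  = TP / (TP + FN)
    Pr  = TP / (TP + FP)
    F1  = 2 * Pr * Sn / (Pr + Sn)

A ratio with zero denominator is reported as 0 with a warning (live for
rare classes with zero predicted positives).  CV metrics pool the
one-vs-rest counts over folds before applying the formulas; per-fold
rows are retained alongside.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

from mlocpred.modeling import PipelineConfig, TrainedModel, fit_pipeline
from mlocpred.seqio import LOCALES, LabeledRecord

METRIC_NAMES = ("precision", "sensitivity", "accuracy", "specificity", "f1")


@dataclass(frozen=True)
class ClassBinaryCounts:
    """One-vs-rest counts for a single class."""

    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.FP, self.TN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN

    def __add__(self, other: "ClassBinaryCounts") -> "ClassBinaryCounts":
        return ClassBinaryCounts(
            self.TP + other.TP,
            self.FN + other.FN,
            self.FP + other.FP,
            self.TN + other.TN,
        )


@dataclass(frozen=True)
class MetricRow:
    """Pr / Sn / Acc / Sp / F1 for one class (or a macro average)."""

    precision: float
    sensitivity: float
    accuracy: float
    specificity: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in METRIC_NAMES}

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Display rounding (2 dp by convention); raw values retained."""
        return {n: round(getattr(self, n), ndigits) for n in METRIC_NAMES}


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, reporting 0", stacklevel=3)
        return 0.0
    return num / den


def metrics_from_counts(cts: ClassBinaryCounts) -> MetricRow:
    """Compute the five one-vs-rest metrics from binary counts."""
    if cts.total == 0:
        raise ValueError("no evaluated samples")
    pr = _safe_ratio(cts.TP, cts.TP + cts.FP, "precision")
    sn = _safe_ratio(cts.TP, cts.TP + cts.FN, "sensitivity")
    sp = _safe_ratio(cts.TN, cts.FP + cts.TN, "specificity")
    acc = (cts.TP + cts.TN) / cts.total
    f1 = _safe_ratio(2 * pr * sn, pr + sn, "f1")
    return MetricRow(precision=pr, sensitivity=sn, accuracy=acc, specificity=sp, f1=f1)


def multiclass_confusion(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    class_labels: Sequence[str] = LOCALES,
) -> np.ndarray:
    """Confusion matrix with entry (i, j) = true class i predicted as j."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred differ in length")
    unknown = sorted((set(y_true) | set(y_pred)) - set(class_labels))
    if unknown:
        raise ValueError(f"labels outside the class list: {unknown}")
    return confusion_matrix(y_true, y_pred, labels=list(class_labels))


def per_class_counts(conf: np.ndarray, class_index: int) -> ClassBinaryCounts:
    """Collapse a multiclass confusion matrix to one-vs-rest counts."""
    conf = np.asarray(conf)
    n = int(conf.sum())
    tp = int(conf[class_index, class_index])
    fn = int(conf[class_index, :].sum()) - tp
    fp = int(conf[:, class_index].sum()) - tp
    tn = n - tp - fn - fp
    return ClassBinaryCounts(TP=tp, FN=fn, FP=fp, TN=tn)


def macro_average(rows: Sequence[MetricRow]) -> MetricRow:
    """Unweighted mean of per-class metric rows (class-order invariant)."""
    if len(rows) != 5:
        raise ValueError(f"expected exactly five class rows, got {len(rows)}")
    return MetricRow(
        **{
            n: float(np.mean([getattr(r, n) for r in rows]))
            for n in METRIC_NAMES
        }
    )


@dataclass
class EvaluationReport:
    """Per-class metric rows plus the macro average, with optional CV detail."""

    class_labels: list[str]
    per_class: dict[str, MetricRow]
    macro: MetricRow
    confusion: np.ndarray
    per_fold: list[dict[str, MetricRow]] = field(default_factory=list)
    oof_true: list[str] = field(default_factory=list)
    oof_pred: list[str] = field(default_factory=list)
    fold_normalizer_means: list[np.ndarray] = field(default_factory=list)

    def to_frame(self, ndigits: int | None = 2) -> pd.DataFrame:
        rows = {c: self.per_class[c].as_dict() for c in self.class_labels}
        rows["Avg"] = self.macro.as_dict()
        df = pd.DataFrame(rows).T[list(METRIC_NAMES)]
        df.columns = ["Pr", "Sn", "Acc", "Sp", "F1"]
        return df.round(ndigits) if ndigits is not None else df

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "class"
        df.to_csv(path, sep="\t")

    def write_json(self, path: str | Path) -> None:
        payload = {
            "per_class": {c: r.as_dict() for c, r in self.per_class.items()},
            "macro": self.macro.as_dict(),
            "confusion": self.confusion.tolist(),
            "class_labels": self.class_labels,
            "per_fold": [
                {c: r.as_dict() for c, r in fold.items()} for fold in self.per_fold
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def evaluate_predictions(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    class_labels: Sequence[str] = LOCALES,
) -> EvaluationReport:
    """Per-class + macro report from predicted labels."""
    conf = multiclass_confusion(y_true, y_pred, class_labels)
    per_class = {
        c: metrics_from_counts(per_class_counts(conf, i))
        for i, c in enumerate(class_labels)
    }
    rows = list(per_class.values())
    if len(rows) == 5:
        macro = macro_average(rows)
    else:  # generic class lists (macro_average is pinned to the 5 locales)
        macro = MetricRow(
            **{n: float(np.mean([getattr(r, n) for r in rows])) for n in METRIC_NAMES}
        )
    return EvaluationReport(
        class_labels=list(class_labels),
        per_class=per_class,
        macro=macro,
        confusion=conf,
    )


def stratified_holdout_split(
    records: Sequence[LabeledRecord],
    test_fraction: float = 1 / 6,
    seed: int = 42,
) -> tuple[list[LabeledRecord], list[LabeledRecord]]:
    """Per-class holdout split (default five-sixths train, one-sixth test).

    The per-class test count is round(n_c * test_fraction); partitions
    are disjoint, exhaustive, and deterministic given the seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[LabeledRecord]] = {}
    for r in records:
        by_class.setdefault(r.label, []).append(r)
    min_size = int(np.ceil(1 / test_fraction))
    train: list[LabeledRecord] = []
    test: list[LabeledRecord] = []
    for label in sorted(by_class):
        members = by_class[label]
        if len(members) < min_size:
            raise ValueError(
                f"class {label!r} has only {len(members)} members; "
                f"need at least {min_size} for a {test_fraction:.3f} holdout"
            )
        n_test = int(round(len(members) * test_fraction))
        n_test = max(1, min(n_test, len(members) - 1))
        order = rng.permutation(len(members))
        test.extend(members[i] for i in order[:n_test])
        train.extend(members[i] for i in order[n_test:])
    return train, test


def holdout_evaluate(
    config: PipelineConfig,
    records: Sequence[LabeledRecord],
    test_fraction: float = 1 / 6,
    seed: int = 42,
    class_labels: Sequence[str] = LOCALES,
) -> tuple[TrainedModel, EvaluationReport]:
    """Train on the five-sixths split and evaluate on the held-out sixth."""
    train, test = stratified_holdout_split(records, test_fraction, seed)
    model = fit_pipeline(config, train, class_labels=class_labels)
    m, failures = model.preprocess_sequences([r.sequence for r in test])
    if failures:
        raise ValueError(f"test records failed encoding: {failures[:3]}")
    preds = model.predict_matrix(m)
    report = evaluate_predictions(
        [r.label for r in test],
        list(preds["predicted_label"]),
        class_labels=class_labels,
    )
    return model, report


def kfold_cv(
    config: PipelineConfig,
    records: Sequence[LabeledRecord],
    folds: int = 5,
    seed: int = 42,
    class_labels: Sequence[str] = LOCALES,
) -> EvaluationReport:
    """Stratified k-fold CV refitting the full pipeline per fold.

    Selection and normalization are fitted on the training folds only
    (no leakage); per-class counts are pooled over folds before the
    metric formulas are applied, and per-fold rows are kept alongside.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labels = [r.label for r in records]
    counts = pd.Series(labels).value_counts()
    too_small = counts[counts < folds]
    if len(too_small):
        raise ValueError(
            f"classes smaller than {folds}: {dict(too_small)}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    idx = np.arange(len(records))
    pooled = np.zeros((len(class_labels), len(class_labels)), dtype=int)
    per_fold: list[dict[str, MetricRow]] = []
    oof_true: list[str] = []
    oof_pred: list[str] = []
    fold_means: list[np.ndarray] = []
    for train_idx, test_idx in skf.split(idx, labels):
        train = [records[i] for i in train_idx]
        test = [records[i] for i in test_idx]
        model = fit_pipeline(config, train, class_labels=class_labels)
        fold_means.append(model.normalizer.means.copy())
        m, failures = model.preprocess_sequences([r.sequence for r in test])
        if failures:
            raise ValueError(f"fold test records failed encoding: {failures[:3]}")
        preds = model.predict_matrix(m)
        y_true = [r.label for r in test]
        y_pred = list(preds["predicted_label"])
        conf = multiclass_confusion(y_true, y_pred, class_labels)
        pooled += conf
        per_fold.append(
            {
                c: metrics_from_counts(per_class_counts(conf, i))
                for i, c in enumerate(class_labels)
            }
        )
        oof_true.extend(y_true)
        oof_pred.extend(y_pred)
    per_class = {
        c: metrics_from_counts(per_class_counts(pooled, i))
        for i, c in enumerate(class_labels)
    }
    macro = macro_average(list(per_class.values()))
    return EvaluationReport(
        class_labels=list(class_labels),
        per_class=per_class,
        macro=macro,
        confusion=pooled,
        per_fold=per_fold,
        oof_true=oof_true,
        oof_pred=oof_pred,
        fold_normalizer_means=fold_means,
    )
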