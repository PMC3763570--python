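"""Evaluation protocols and summary statistics.

Per class s, with one-vs-rest confusion counts TP, TN, FP, FN over N test
predictions:

    Acc_s = TP_s / (TP_s + FN_s)                       (class recall)
    MCC_s = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    ACC   = sum_s TP_s / sum_s (TP_s + FN_s)           (overall accuracy)

MCC_s equals the Pearson correlation of the binary indicator vectors
"truth is class s" vs "prediction is class s"; when its denominator is zero
(a degenerate predictor or class) it is reported as 0 by convention.  The
jackknife protocol is leave-one-out: each sample is predicted by a model
trained on all others with fixed hyperparameters.  The hold-out protocol
draws unstratified random train subsets and evaluates on the complement,
repeated with per-repeat seeds spawned from a master seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone

from .classifier import LocationSVC, ModelConfig

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    """Raised for evaluation protocol precondition failures."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class one-vs-rest confusion counts, in fixed class order."""

    classes: tuple[str, ...]
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.classes)
        for name in ("tp", "tn", "fp", "fn"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if arr.shape != (n,) or np.any(arr < 0):
                raise EvaluationError(f"{name} must be {n} nonnegative counts")
            object.__setattr__(self, name, arr)
        totals = self.tp + self.tn + self.fp + self.fn
        if n and np.any(totals != totals[0]):
            raise EvaluationError("per-class counts must share the same total N")

    @property
    def n_total(self) -> int:
        return int(self.tp[0] + self.tn[0] + self.fp[0] + self.fn[0])

    @classmethod
    def from_labels(cls, y_true, y_pred, classes=None) -> "ConfusionCounts":
        y_true = [str(v) for v in y_true]
        y_pred = [str(v) for v in y_pred]
        if len(y_true) != len(y_pred):
            raise EvaluationError("y_true and y_pred differ in length")
        if classes is None:
            classes = sorted(set(y_true) | set(y_pred))
        classes = tuple(str(c) for c in classes)
        n = len(y_true)
        tp, tn, fp, fn = (np.zeros(len(classes), dtype=np.int64) for _ in range(4))
        for s, c in enumerate(classes):
            for t, p in zip(y_true, y_pred):
                if t == c and p == c:
                    tp[s] += 1
                elif t == c:
                    fn[s] += 1
                elif p == c:
                    fp[s] += 1
                else:
                    tn[s] += 1
        counts = cls(classes, tp, tn, fp, fn)
        assert counts.n_total == n
        return counts


@dataclass
class EvaluationReport:
    """Per-class Acc/MCC, overall ACC, and the underlying counts."""

    counts: ConfusionCounts
    acc_per_class: dict[str, float]
    mcc_per_class: dict[str, float]
    overall_acc: float
    protocol: str = ""
    config: ModelConfig | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "classes": list(self.counts.classes),
            # NaN (class absent from the truth) serializes as null
            "acc_per_class": {
                c: (None if math.isnan(v) else v)
                for c, v in self.acc_per_class.items()
            },
            "mcc_per_class": self.mcc_per_class,
            "overall_acc": self.overall_acc,
            "counts": {
                c: {
                    "tp": int(self.counts.tp[s]),
                    "tn": int(self.counts.tn[s]),
                    "fp": int(self.counts.fp[s]),
                    "fn": int(self.counts.fn[s]),
                }
                for s, c in enumerate(self.counts.classes)
            },
            **self.extra,
        }

    def format_table(self) -> str:
        """Human-readable table: one row per class plus overall, percentages
        to two decimals."""
        lines = [f"{'Location':<20}{'ACC':>10}{'MCC':>8}"]
        for c in self.counts.classes:
            acc = self.acc_per_class[c]
            acc_s = "   n/a" if math.isnan(acc) else f"{100 * acc:.2f}%"
            lines.append(f"{c:<20}{acc_s:>10}{self.mcc_per_class[c]:>8.2f}")
        lines.append(f"{'Overall':<20}{100 * self.overall_acc:.2f}%")
        return "\n".join(lines)


def confusion_metrics(
    counts: ConfusionCounts, protocol: str = "", config: ModelConfig | None = None
) -> EvaluationReport:
    """Per-class accuracy and MCC plus overall accuracy from counts.

    A class never present in the truth (TP + FN = 0) has undefined accuracy;
    it is reported as NaN with a warning, never silently as 0.  An MCC whose
    denominator vanishes is 0 by convention.
    """
    acc: dict[str, float] = {}
    mcc: dict[str, float] = {}
    for s, c in enumerate(counts.classes):
        tp, tn = float(counts.tp[s]), float(counts.tn[s])
        fp, fn = float(counts.fp[s]), float(counts.fn[s])
        if tp + fn == 0:
            logger.warning("class %r absent from the truth; Acc undefined", c)
            acc[c] = float("nan")
        else:
            acc[c] = tp / (tp + fn)
        denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc[c] = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
    total_pos = float(counts.tp.sum() + counts.fn.sum())
    if total_pos == 0:
        raise EvaluationError("no test predictions to evaluate")
    overall = float(counts.tp.sum()) / total_pos
    return EvaluationReport(counts, acc, mcc, overall, protocol, config)


def _default_estimator(config: ModelConfig | None):
    if config is None:
        return LocationSVC()
    return LocationSVC(gamma=config.gamma, C=config.C)


def jackknife(
    X, y, model_config: ModelConfig | None = None, estimator=None
) -> EvaluationReport:
    """Leave-one-out evaluation with fixed hyperparameters.

    Any scikit-learn classifier may stand in via ``estimator``; the default
    is the RBF-SVM at ``model_config``'s operating point.  Deterministic
    end-to-end.

    Raises
    ------
    EvaluationError
        If N < number of classes + 1 or any class has fewer than 2 members
        (a singleton class would vanish from its own training fold).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray([str(v) for v in y])
    n = X.shape[0]
    classes, counts_per_class = np.unique(y, return_counts=True)
    if n < classes.size + 1:
        raise EvaluationError(
            f"jackknife needs N >= n_classes + 1 (N={n}, classes={classes.size})"
        )
    singletons = classes[counts_per_class < 2].tolist()
    if singletons:
        raise EvaluationError(
            f"classes with fewer than 2 members cannot be jackknifed: {singletons}"
        )
    base = estimator if estimator is not None else _default_estimator(model_config)
    preds = np.empty(n, dtype=object)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        est = clone(base)
        est.fit(X[mask], y[mask])
        preds[i] = str(est.predict(X[i : i + 1])[0])
        mask[i] = True
    counts = ConfusionCounts.from_labels(y, preds, classes=classes.tolist())
    return confusion_metrics(counts, protocol="jackknife", config=model_config)


@dataclass
class HoldoutResult:
    """Repeated random-split evaluation summary."""

    mean_acc: float
    sd_acc: float
    reports: list[EvaluationReport]
    repeat_seeds: list[int]


def holdout_test(
    X,
    y,
    model_config: ModelConfig | None = None,
    train_fraction: float = 0.8,
    repeats: int = 20,
    seed: int = 0,
    estimator=None,
    max_redraws: int = 100,
) -> HoldoutResult:
    """Repeated unstratified hold-out evaluation.

    Each repeat draws round(train_fraction * N) training rows uniformly at
    random, trains, and evaluates on the complement.  A draw whose training
    set misses a class (possible without stratification) is redrawn with a
    logged warning, up to ``max_redraws`` times.  The across-repeat standard
    deviation is the population sd (divide by ``repeats``).
    """
    if not (0.0 < train_fraction < 1.0):
        raise EvaluationError(f"train_fraction must be in (0, 1): {train_fraction}")
    if repeats < 1:
        raise EvaluationError("repeats must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray([str(v) for v in y])
    n = X.shape[0]
    n_train = int(round(train_fraction * n))
    if n_train < 1 or n_train >= n:
        raise EvaluationError(
            f"train_fraction {train_fraction} leaves an empty split for N={n}"
        )
    classes = set(np.unique(y))
    base = estimator if estimator is not None else _default_estimator(model_config)
    master = np.random.SeedSequence(seed)
    repeat_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(repeats)]
    reports: list[EvaluationReport] = []
    accs = []
    for r, rep_seed in enumerate(repeat_seeds):
        rng = np.random.default_rng(rep_seed)
        for attempt in range(max_redraws + 1):
            train_idx = rng.choice(n, size=n_train, replace=False)
            if set(y[train_idx]) == classes:
                break
            logger.warning(
                "repeat %d draw %d misses a class in training; redrawing", r, attempt
            )
        else:
            raise EvaluationError(
                f"repeat {r}: could not draw a training set covering all classes"
            )
        test_mask = np.ones(n, dtype=bool)
        test_mask[train_idx] = False
        est = clone(base)
        est.fit(X[train_idx], y[train_idx])
        preds = [str(p) for p in est.predict(X[test_mask])]
        counts = ConfusionCounts.from_labels(
            y[test_mask], preds, classes=sorted(classes)
        )
        report = confusion_metrics(counts, protocol="holdout", config=model_config)
        report.extra["repeat_seed"] = rep_seed
        reports.append(report)
        accs.append(report.overall_acc)
    accs = np.asarray(accs)
    return HoldoutResult(
        mean_acc=float(accs.mean()),
        sd_acc=float(accs.std()),  # population sd
        reports=reports,
        repeat_seeds=repeat_seeds,
    )
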