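"""Confusion-matrix diagnostics and the MAPE-vs-epoch curve.

Per-class metrics use the one-vs-rest reduction: for class ``c`` a true
positive is a row of class ``c`` predicted ``c``, a true negative a row of
any other class predicted as any other class, and so on.  Rates with an
empty denominator (e.g. sensitivity of a class absent from the truth) are
reported as NaN with an explicit ``defined`` flag, never coerced to 0.

MAPE (mean absolute percentage error) is computed on numeric class codes by
default: ``100/n * sum(|t_i - p_i| / |t_i|)``.  Class codes are 1-4, so the
denominator never vanishes under that encoding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

__all__ = [
    "ClassMetrics",
    "EvalReport",
    "confusion_matrix",
    "evaluate",
    "mape",
    "mape_curve",
]

N_CLASSES = 4


@dataclass
class ClassMetrics:
    """One-vs-rest counts and rates for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_defined: bool
    specificity_defined: bool

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "sensitivity": None if not self.sensitivity_defined else self.sensitivity,
            "specificity": None if not self.specificity_defined else self.specificity,
            "accuracy": self.accuracy,
        }


@dataclass
class EvalReport:
    confusion: np.ndarray
    per_class: dict[int, ClassMetrics]
    n: int
    overall_accuracy: float
    mape: float | None = None
    mape_curve: list[tuple[int, float]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "confusion": self.confusion.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "per_class": {c: m.as_dict() for c, m in self.per_class.items()},
            "mape": self.mape,
            "mape_curve": [list(p) for p in self.mape_curve],
        }


def _check_labels(true_labels, predicted_labels):
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape or t.ndim != 1:
        raise InputError("true and predicted labels must be equal-length vectors")
    for name, v in (("true", t), ("predicted", p)):
        if ((v < 1) | (v > N_CLASSES)).any():
            raise InputError(f"{name} labels outside 1..{N_CLASSES}")
    return t, p


def confusion_matrix(true_labels, predicted_labels) -> np.ndarray:
    """4x4 count matrix; rows = true class, columns = predicted class."""
    t, p = _check_labels(true_labels, predicted_labels)
    conf = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(conf, (t - 1, p - 1), 1)
    return conf


def _rate(num: int, den: int) -> tuple[float, bool]:
    if den == 0:
        return math.nan, False
    return num / den, True


def evaluate(true_labels, predicted_labels) -> EvalReport:
    """Confusion matrix plus one-vs-rest sensitivity/specificity/accuracy."""
    conf = confusion_matrix(true_labels, predicted_labels)
    n = int(conf.sum())
    per_class: dict[int, ClassMetrics] = {}
    for c in range(1, N_CLASSES + 1):
        i = c - 1
        tp = int(conf[i, i])
        fn = int(conf[i].sum() - tp)
        fp = int(conf[:, i].sum() - tp)
        tn = n - tp - fn - fp
        sens, sens_ok = _rate(tp, tp + fn)
        spec, spec_ok = _rate(tn, tn + fp)
        per_class[c] = ClassMetrics(
            tp=tp,
            tn=tn,
            fp=fp,
            fn=fn,
            sensitivity=sens,
            specificity=spec,
            accuracy=(tp + tn) / n,
            sensitivity_defined=sens_ok,
            specificity_defined=spec_ok,
        )
    return EvalReport(
        confusion=conf,
        per_class=per_class,
        n=n,
        overall_accuracy=float(np.trace(conf)) / n,
    )


def mape(targets, predictions) -> float:
    """Mean absolute percentage error, as a percentage."""
    t = np.asarray(targets, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise InputError("targets and predictions must be equal-length vectors")
    if (t == 0).any():
        raise InputError(
            "zero target encountered; MAPE is undefined under an encoding "
            "that produces zero targets"
        )
    return float(100.0 / t.size * np.sum(np.abs(t - p) / np.abs(t)))


def mape_curve(
    train_table,
    test_table,
    epoch_budgets,
    cfg=None,
    hidden: tuple[int, ...] = (50, 25, 5),
    mode: str = "scg",
    eligibility=None,
) -> list[tuple[int, float]]:
    """MAPE on held-out class codes as a function of the training budget.

    Retrains the cascade from the same seed with ``max_epochs`` capped at
    each budget and scores the test table, mirroring how error-vs-epoch
    tables are produced for iterative learners.
    """
    from .cascade import cascade_predict_table, cascade_train
    from .neural import TrainConfig

    cfg = cfg or TrainConfig()
    curve: list[tuple[int, float]] = []
    for budget in epoch_budgets:
        stage_cfg = TrainConfig(
            max_epochs=int(budget),
            goal_mse=cfg.goal_mse,
            seed=cfg.seed,
            sigma0=cfg.sigma0,
            lambda0=cfg.lambda0,
            patience=max(cfg.patience, int(budget)),
            ridge=cfg.ridge,
        )
        model = cascade_train(train_table, stage_cfg, hidden=hidden, mode=mode)
        pred = cascade_predict_table(model, test_table, eligibility=eligibility)
        curve.append((int(budget), mape(test_table.labels, pred)))
    return curve
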