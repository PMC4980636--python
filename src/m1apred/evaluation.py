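"""Metrics and validation protocols for the m1A site classifier.

Four threshold-based metrics are computed from the confusion counts:

.. math::

    Sn  = TP / (TP + FN) \\qquad
    Sp  = TN / (TN + FP) \\qquad
    Acc = (TP + TN) / (TP + TN + FP + FN)

    MCC = \\frac{TP \\cdot TN - FP \\cdot FN}
               {\\sqrt{(TP+FP)(TP+FN)(TN+FP)(TN+FN)}}

Sn, Sp and Acc are reported as percentages; MCC lies in [-1, 1] and is
reported as NaN (with a warning) when any marginal is empty rather than
being clamped to 0.  Threshold-free quality is measured by ROC / AUROC and
precision-recall / AUPRC computed from the continuous SVM decision values.

Three validation protocols are provided:

* **jackknife** — leave-one-out: every window is scored by a model trained
  on all the others.  By default the (C, gamma) pair is selected once on
  the full dataset and held fixed across folds; ``nested=True`` repeats the
  grid search inside every fold (leakage-free but n-times more expensive).
* **k-fold** — stratified k-fold cross-validation (default k=10) with
  seed-derived shuffling; hyperparameter handling as above.
* **cross-dataset** — train once on one dataset, score another; used for
  cross-cell-line and cross-species generalization matrices.

An ablation runner evaluates the four feature channels (ring structure,
hydrogen bond, chemical functionality, density) one at a time and combined.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold

from ._errors import CompatibilityError, EvaluationError, ParameterError
from .classifier import (
    SVMConfig,
    TrainedModel,
    grid_search_train,
    make_svm,
    select_hyperparameters,
)
from .feature_encoding import CHANNELS, FeatureMask, encode_dataset
from .sequence_io import WindowDataset


class UndefinedMCCWarning(UserWarning):
    """MCC denominator is zero (an empty confusion-matrix marginal)."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_calls(
        cls, predicted: Sequence[int], truth: Sequence[int]
    ) -> "ConfusionCounts":
        p = np.asarray(predicted, dtype=int)
        t = np.asarray(truth, dtype=int)
        return cls(
            TP=int(((p == 1) & (t == 1)).sum()),
            TN=int(((p == 0) & (t == 0)).sum()),
            FP=int(((p == 1) & (t == 0)).sum()),
            FN=int(((p == 0) & (t == 1)).sum()),
        )


def compute_metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(Sn, Sp, Acc, MCC) from confusion counts; Sn/Sp/Acc in percent.

    Any undefined ratio (empty marginal) is NaN; an undefined MCC
    additionally emits :class:`UndefinedMCCWarning`.
    """
    if counts.total == 0:
        raise ParameterError("cannot compute metrics of an empty evaluation")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    sn = 100.0 * tp / (tp + fn) if tp + fn else math.nan
    sp = 100.0 * tn / (tn + fp) if tn + fp else math.nan
    acc = 100.0 * (tp + tn) / counts.total
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if denom == 0.0:
        warnings.warn(
            "MCC undefined: one confusion-matrix marginal is empty",
            UndefinedMCCWarning,
            stacklevel=2,
        )
        mcc = math.nan
    else:
        mcc = (float(tp) * tn - float(fp) * fn) / denom
    return sn, sp, acc, mcc


def roc_pr_curves(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """ROC and PR curves with their areas from continuous scores.

    The ROC curve sweeps thresholds over the unique scores (descending),
    runs from (0, 0) to (1, 1), and its area is the trapezoidal integral —
    numerically identical to the Mann-Whitney U statistic divided by
    ``n_pos * n_neg``.  The PR area uses the step-wise
    (precision-at-recall-change) convention rather than trapezoidal
    interpolation, which would be optimistic.

    Returns (roc_points, pr_points, AUROC, AUPRC) where the point arrays
    have columns (FPR, TPR) and (recall, precision) respectively.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise EvaluationError("ROC/PR need scores from both classes")
    fpr, tpr, _ = roc_curve(y, s)
    auroc = float(auc(fpr, tpr))
    precision, recall, _ = precision_recall_curve(y, s)
    auprc = float(average_precision_score(y, s))
    roc_points = np.column_stack([fpr, tpr])
    pr_points = np.column_stack([recall[::-1], precision[::-1]])
    return roc_points, pr_points, auroc, auprc


@dataclass
class EvalReport:
    """Everything one validation run produced, recomputable from its parts."""

    counts: ConfusionCounts
    Sn: float
    Sp: float
    Acc: float
    MCC: float
    AUROC: float
    AUPRC: float
    roc_points: np.ndarray = field(repr=False)
    pr_points: np.ndarray = field(repr=False)
    scheme: str = ""
    seed: int = 0
    train_tag: str = ""
    test_tag: str = ""
    selected_C: float | None = None
    selected_gamma: float | None = None
    scores: np.ndarray | None = field(default=None, repr=False)
    labels: np.ndarray | None = field(default=None, repr=False)
    fold_assignment: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def from_scores(
        cls,
        scores: Sequence[float],
        labels: Sequence[int],
        scheme: str,
        seed: int = 0,
        train_tag: str = "",
        test_tag: str = "",
        selected_C: float | None = None,
        selected_gamma: float | None = None,
        fold_assignment: np.ndarray | None = None,
    ) -> "EvalReport":
        s = np.asarray(scores, dtype=float)
        y = np.asarray(labels, dtype=int)
        calls = (s > 0).astype(int)
        counts = ConfusionCounts.from_calls(calls, y)
        sn, sp, accu, mcc = compute_metrics(counts)
        roc_pts, pr_pts, auroc, auprc = roc_pr_curves(s, y)
        return cls(
            counts=counts,
            Sn=sn,
            Sp=sp,
            Acc=accu,
            MCC=mcc,
            AUROC=auroc,
            AUPRC=auprc,
            roc_points=roc_pts,
            pr_points=pr_pts,
            scheme=scheme,
            seed=seed,
            train_tag=train_tag,
            test_tag=test_tag,
            selected_C=selected_C,
            selected_gamma=selected_gamma,
            scores=s,
            labels=y,
            fold_assignment=fold_assignment,
        )

    def summary(self) -> dict:
        return {
            "scheme": self.scheme,
            "train_tag": self.train_tag,
            "test_tag": self.test_tag,
            "TP": self.counts.TP,
            "TN": self.counts.TN,
            "FP": self.counts.FP,
            "FN": self.counts.FN,
            "Sn_percent": self.Sn,
            "Sp_percent": self.Sp,
            "Acc_percent": self.Acc,
            "MCC": self.MCC,
            "AUROC": self.AUROC,
            "AUPRC": self.AUPRC,
            "selected_C": self.selected_C,
            "selected_gamma": self.selected_gamma,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = self.summary()
        payload["auprc_convention"] = "step (precision at recall change)"
        payload["roc_points"] = self.roc_points.tolist()
        payload["pr_points"] = self.pr_points.tolist()
        if self.fold_assignment is not None:
            payload["fold_assignment"] = self.fold_assignment.tolist()
        text = json.dumps(payload, indent=2, allow_nan=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _encoded(dataset: WindowDataset, mask: FeatureMask | None):
    mask = mask or FeatureMask.full()
    X = encode_dataset(dataset.records, mask, dataset.window_length)
    y = np.asarray(dataset.labels())
    return X, y, mask


def jackknife_evaluate(
    dataset: WindowDataset,
    config: SVMConfig | None = None,
    mask: FeatureMask | None = None,
    nested: bool = False,
) -> EvalReport:
    """Leave-one-out evaluation: each window scored by a model trained on the rest.

    ``nested=False`` (default) selects (C, gamma) once on the full dataset
    and reuses the pair in every fold; ``nested=True`` re-runs the grid
    search inside each fold.
    """
    config = config or SVMConfig()
    X, y, mask = _encoded(dataset, mask)
    if min(np.bincount(y, minlength=2)) < 2:
        raise EvaluationError("jackknife needs at least 2 windows per class")
    if not nested:
        C, gamma, _ = select_hyperparameters(X, y, config)
    scores = np.empty(len(y))
    idx = np.arange(len(y))
    for i in idx:
        train = idx != i
        if nested:
            C, gamma, _ = select_hyperparameters(X[train], y[train], config)
        est = make_svm(C, gamma, config.seed).fit(X[train], y[train])
        scores[i] = est.decision_function(X[i : i + 1])[0]
    return EvalReport.from_scores(
        scores,
        y,
        scheme="jackknife" + ("-nested" if nested else ""),
        seed=config.seed,
        train_tag=dataset.tag,
        test_tag=dataset.tag,
        selected_C=None if nested else C,
        selected_gamma=None if nested else gamma,
    )


def kfold_evaluate(
    dataset: WindowDataset,
    k: int = 10,
    config: SVMConfig | None = None,
    mask: FeatureMask | None = None,
    seed: int | None = None,
    nested: bool = False,
) -> EvalReport:
    """Stratified k-fold cross-validation (default k=10).

    Fold assignment is shuffled with ``seed`` (defaults to the SVM config
    seed) and recorded in the report.  The union of held-out folds covers
    the dataset exactly once.
    """
    config = config or SVMConfig()
    if seed is None:
        seed = config.seed
    if k < 2:
        raise ParameterError("k must be >= 2")
    X, y, mask = _encoded(dataset, mask)
    if min(np.bincount(y, minlength=2)) < k:
        raise EvaluationError(
            f"each class needs at least k={k} members for stratified k-fold"
        )
    if not nested:
        C, gamma, _ = select_hyperparameters(X, y, config)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    assignment = np.empty(len(y), dtype=int)
    for fold, (train, test) in enumerate(cv.split(X, y)):
        if nested:
            C, gamma, _ = select_hyperparameters(X[train], y[train], config)
        est = make_svm(C, gamma, config.seed).fit(X[train], y[train])
        scores[test] = est.decision_function(X[test])
        assignment[test] = fold
    return EvalReport.from_scores(
        scores,
        y,
        scheme=f"kfold({k})" + ("-nested" if nested else ""),
        seed=seed,
        train_tag=dataset.tag,
        test_tag=dataset.tag,
        selected_C=None if nested else C,
        selected_gamma=None if nested else gamma,
        fold_assignment=assignment,
    )


def cross_evaluate(
    train: WindowDataset,
    test: WindowDataset,
    config: SVMConfig | None = None,
    mask: FeatureMask | None = None,
    model: TrainedModel | None = None,
) -> EvalReport:
    """Train on one dataset and score another (independent test).

    Used for cross-cell-line and cross-species generalization; a
    pre-trained ``model`` can be supplied to fill a whole train-by-test
    matrix without refitting.  Overlapping sequences between train and test
    trigger a warning (not an error).
    """
    if train.window_length != test.window_length:
        raise CompatibilityError(
            f"window lengths differ: train {train.window_length} vs "
            f"test {test.window_length}"
        )
    overlap = {r.seq for r in train.records} & {r.seq for r in test.records}
    if overlap:
        warnings.warn(
            f"{len(overlap)} sequence(s) shared between train and test sets",
            UserWarning,
            stacklevel=2,
        )
    if model is None:
        model = grid_search_train(train, config, mask)
    X = encode_dataset(test.records, model.feature_mask, test.window_length)
    scores = model.estimator.decision_function(X)
    return EvalReport.from_scores(
        scores,
        np.asarray(test.labels()),
        scheme="independent",
        seed=model.seed,
        train_tag=train.tag,
        test_tag=test.tag,
        selected_C=model.selected_C,
        selected_gamma=model.selected_gamma,
    )


def cross_matrix(
    datasets: Sequence[WindowDataset],
    config: SVMConfig | None = None,
    mask: FeatureMask | None = None,
) -> pd.DataFrame:
    """Accuracy matrix: train on each dataset (rows), test on each (columns)."""
    models = [grid_search_train(d, config, mask) for d in datasets]
    rows = {}
    for d_train, model in zip(datasets, models):
        row = {}
        for d_test in datasets:
            rep = cross_evaluate(d_train, d_test, config, mask, model=model)
            row[d_test.tag] = rep.Acc
        rows[d_train.tag] = row
    return pd.DataFrame(rows).T


ABLATION_MASKS: dict[str, FeatureMask] = {
    **{ch: FeatureMask.only(ch) for ch in CHANNELS},
    "all": FeatureMask.full(),
}


def ablation_study(
    dataset: WindowDataset,
    config: SVMConfig | None = None,
    k: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """k-fold evaluation per feature channel plus the combined encoding.

    One row per mask (ring, hbond, functionality, density, all), columns
    are the metric suite — the per-channel contribution comparison.
    """
    rows = []
    for name, mask in ABLATION_MASKS.items():
        rep = kfold_evaluate(dataset, k=k, config=config, mask=mask, seed=seed)
        rows.append(
            {
                "mask": name,
                "Sn_percent": rep.Sn,
                "Sp_percent": rep.Sp,
                "Acc_percent": rep.Acc,
                "MCC": rep.MCC,
                "AUROC": rep.AUROC,
                "AUPRC": rep.AUPRC,
            }
        )
    return pd.DataFrame(rows)


def plot_curves(report: EvalReport, path: str | Path) -> None:
    """Write a two-panel ROC / PR figure for one report."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(report.roc_points[:, 0], report.roc_points[:, 1])
    ax1.plot([0, 1], [0, 1], ls="--", c="gray")
    ax1.set_xlabel("False positive rate")
    ax1.set_ylabel("True positive rate")
    ax1.set_title(f"ROC (AUROC={report.AUROC:.3f})")
    ax2.plot(report.pr_points[:, 0], report.pr_points[:, 1], drawstyle="steps-post")
    ax2.set_xlabel("Recall")
    ax2.set_ylabel("Precision")
    ax2.set_title(f"PR (AUPRC={report.AUPRC:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
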