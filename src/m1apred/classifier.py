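"""RBF-kernel support-vector classification with grid-searched C and gamma.

The classifier is a standard soft-margin SVM with a radial basis kernel.
Hyperparameters are chosen by exhaustive grid search: for every (C, gamma)
pair the stratified inner-CV accuracy is computed, the best pair wins, and
the final model is refit on the full training set.  Ties are broken toward
the smallest C, then the smallest gamma, which makes the winner independent
of grid enumeration order.

Features produced by the chemical-property/density encoder already lie in
[0, 1], so no additional scaling is applied.

Default grids follow the usual practitioner convention for RBF-SVM search:
``C in 2^-5, 2^-3, ..., 2^15`` and ``gamma in 2^-15, 2^-13, ..., 2^3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from ._errors import (
    CompatibilityError,
    ModelIOError,
    ParameterError,
    TrainingError,
)
from .feature_encoding import FeatureMask, encode_dataset
from .sequence_io import SequenceRecord, WindowDataset, validate_window

MODEL_FORMAT_VERSION = 1

DEFAULT_C_GRID = tuple(float(2.0**e) for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(float(2.0**e) for e in range(-15, 4, 2))


def _check_grid(name: str, grid: tuple[float, ...]) -> tuple[float, ...]:
    grid = tuple(float(v) for v in grid)
    if not grid:
        raise ParameterError(f"{name} grid must be nonempty")
    if any(v <= 0 for v in grid):
        raise ParameterError(f"{name} grid values must be strictly positive")
    if list(grid) != sorted(grid):
        raise ParameterError(f"{name} grid must be sorted ascending")
    return grid


@dataclass(frozen=True)
class SVMConfig:
    """Grid-search settings for the RBF-SVM."""

    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    inner_cv_folds: int = 5
    seed: int = 0
    criterion: str = "accuracy"  # or "roc_auc"

    def __post_init__(self) -> None:
        object.__setattr__(self, "C_grid", _check_grid("C", self.C_grid))
        object.__setattr__(
            self, "gamma_grid", _check_grid("gamma", self.gamma_grid)
        )
        if self.inner_cv_folds < 2:
            raise ParameterError("inner_cv_folds must be >= 2")
        if self.criterion not in ("accuracy", "roc_auc"):
            raise ParameterError("criterion must be 'accuracy' or 'roc_auc'")


@dataclass
class TrainedModel:
    """A fitted RBF-SVM plus everything needed to apply it consistently."""

    estimator: SVC
    selected_C: float
    selected_gamma: float
    feature_mask: FeatureMask
    window_length: int
    training_tag: str = ""
    seed: int = 0
    cv_results: pd.DataFrame | None = field(default=None, repr=False)


def make_svm(C: float, gamma: float, seed: int = 0) -> SVC:
    """A bare RBF-SVM with the given hyperparameters (no search)."""
    return SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed)


def select_hyperparameters(
    X: np.ndarray, y: np.ndarray, config: SVMConfig
) -> tuple[float, float, pd.DataFrame]:
    """Grid-search (C, gamma) by stratified inner-CV score.

    Returns the winning pair and the full per-grid-point result table.
    Ties go to the smallest C, then the smallest gamma.
    """
    if len(np.unique(y)) < 2:
        raise TrainingError("training data must contain both classes")
    cv = StratifiedKFold(
        n_splits=config.inner_cv_folds, shuffle=True, random_state=config.seed
    )
    rows = []
    best = (-np.inf, None, None)
    for C in config.C_grid:
        for gamma in config.gamma_grid:
            scores = cross_val_score(
                make_svm(C, gamma, config.seed),
                X,
                y,
                cv=cv,
                scoring=config.criterion,
            )
            mean = float(scores.mean())
            rows.append({"C": C, "gamma": gamma, "cv_score": mean})
            # strict > keeps the earliest (smallest C, then gamma) on ties
            if mean > best[0]:
                best = (mean, C, gamma)
    table = pd.DataFrame(rows)
    return best[1], best[2], table


def grid_search_train(
    dataset: WindowDataset,
    config: SVMConfig | None = None,
    mask: FeatureMask | None = None,
) -> TrainedModel:
    """Select (C, gamma) on ``dataset`` and refit the final model on all of it."""
    config = config or SVMConfig()
    mask = mask or FeatureMask.full()
    X = encode_dataset(dataset.records, mask, dataset.window_length)
    y = np.asarray(dataset.labels())
    C, gamma, table = select_hyperparameters(X, y, config)
    est = make_svm(C, gamma, config.seed).fit(X, y)
    return TrainedModel(
        estimator=est,
        selected_C=C,
        selected_gamma=gamma,
        feature_mask=mask,
        window_length=dataset.window_length,
        training_tag=dataset.tag,
        seed=config.seed,
        cv_results=table,
    )


def predict(
    model: TrainedModel, records: list[SequenceRecord]
) -> pd.DataFrame:
    """Score windows with a trained model.

    Returns a DataFrame with columns ``id``, ``score`` (SVM decision value,
    positive side of the hyperplane is the modified class) and ``call``
    (positive iff score > 0).  Continuous scores, not calls, feed ROC/PR
    analysis.  Scores depend only on each window's sequence, never on the
    order or company of other records.
    """
    for rec in records:
        try:
            validate_window(rec, model.window_length)
        except Exception as exc:
            raise CompatibilityError(
                f"record '{rec.id}' incompatible with model "
                f"(window length {model.window_length}): {exc}"
            ) from exc
    if not records:
        return pd.DataFrame(columns=["id", "score", "call"])
    X = encode_dataset(records, model.feature_mask, model.window_length)
    scores = model.estimator.decision_function(X)
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "score": scores,
            "call": np.where(scores > 0, "positive", "negative"),
        }
    )


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a trained model with its metadata header."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "estimator": model.estimator,
        "selected_C": model.selected_C,
        "selected_gamma": model.selected_gamma,
        "feature_channels": sorted(model.feature_mask.channels),
        "window_length": model.window_length,
        "training_tag": model.training_tag,
        "seed": model.seed,
        "cv_results": model.cv_results,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    """Load a model saved by :func:`save_model`.

    Raises :class:`ModelIOError` on truncated files or unknown formats.
    """
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelIOError(f"cannot read model file {path}: {exc}") from exc
    if (
        not isinstance(payload, dict)
        or payload.get("format_version") != MODEL_FORMAT_VERSION
    ):
        raise ModelIOError(
            f"{path} is not a model file of format version "
            f"{MODEL_FORMAT_VERSION}"
        )
    return TrainedModel(
        estimator=payload["estimator"],
        selected_C=payload["selected_C"],
        selected_gamma=payload["selected_gamma"],
        feature_mask=FeatureMask(frozenset(payload["feature_channels"])),
        window_length=payload["window_length"],
        training_tag=payload["training_tag"],
        seed=payload["seed"],
        cv_results=payload.get("cv_results"),
    )
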