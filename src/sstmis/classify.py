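"""Final emotion classifier C.

Trained on the selected source instances (optionally augmented with the
inverse-mapped labeled calibration rows, which live in the same source
space after the style map is applied) and used to predict emotions for
inverse-mapped unlabeled target features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data import FeatureMatrix
from .instance_selection import SelectedInstances


@dataclass
class EmotionModel:
    """One-vs-one SVM with probability outputs, plus its fitted scaler."""

    pipeline: Pipeline
    classes: np.ndarray
    trained_on: str  # "sel_only" | "sel_plus_mapped_target"

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.pipeline.predict_proba(np.asarray(X, dtype=float))


def train_emotion_model(
    sel: SelectedInstances | FeatureMatrix | np.ndarray,
    y: np.ndarray | None = None,
    mapped_T_L: FeatureMatrix | None = None,
    mode: str = "sel_plus_mapped_target",
    *,
    kernel: str = "linear",
    C: float = 1.0,
    seed: int = 0,
) -> EmotionModel:
    """Train C on selected instances, optionally plus mapped target rows.

    ``mode="sel_plus_mapped_target"`` (default) appends the inverse-mapped
    labeled calibration rows to the training set — they sit in the source
    space after adaptation, so they are legitimate extra labeled data.
    ``mode="sel_only"`` uses only the selected source instances (the
    ablation variant).
    """
    if isinstance(sel, SelectedInstances):
        X, y = sel.X, sel.y
    elif isinstance(sel, FeatureMatrix):
        X, y = sel.X, sel.y if y is None else y
    else:
        X = np.asarray(sel, dtype=float)
    if y is None:
        raise ValueError("labels are required to train the emotion model")
    y = np.asarray(y, dtype=int)

    if mode not in ("sel_only", "sel_plus_mapped_target"):
        raise ValueError(f"unknown training mode {mode!r}")
    if mode == "sel_plus_mapped_target" and mapped_T_L is not None and mapped_T_L.n > 0:
        if mapped_T_L.y is None:
            raise ValueError("mapped target rows must be labeled")
        X = np.vstack([X, mapped_T_L.X])
        y = np.concatenate([y, mapped_T_L.y])

    present = np.unique(y)
    if len(present) < 2:
        raise ValueError(
            f"emotion model needs at least 2 classes, got {present.tolist()}"
        )
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel=kernel, C=C, probability=True, random_state=seed)),
        ]
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*probability.*", category=FutureWarning)
        pipe.fit(X, y)
    return EmotionModel(pipeline=pipe, classes=pipe.classes_, trained_on=mode)


def predict(
    model: EmotionModel, U: FeatureMatrix | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and per-class probabilities for each input row.

    Labels are the argmax of the calibrated probabilities, so they are
    consistent with the returned probability rows (libsvm's raw ``predict``
    can disagree with ``predict_proba`` near ties).
    """
    X = U.X if isinstance(U, FeatureMatrix) else np.asarray(U, dtype=float)
    n_fit = model.pipeline.named_steps["scale"].mean_.shape[0]
    if X.shape[1] != n_fit:
        raise ValueError(f"feature dim {X.shape[1]} does not match model dim {n_fit}")
    if X.shape[0] == 0:
        return np.empty(0, dtype=int), np.empty((0, len(model.classes)))
    proba = model.predict_proba(X)
    labels = model.classes[np.argmax(proba, axis=1)]
    return labels.astype(int), proba
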