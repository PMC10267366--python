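"""Instance selection from the multi-subject source pool.

A probe classifier C0 (one-vs-one SVM with probability outputs) is trained
on the new subject's small labeled calibration set. Every source-domain
sample is then scored by the probability C0 assigns to it — by default the
probability of the sample's own emotion label — and the top-k highest
scoring samples per emotion category are kept. Per-class selection keeps
the retained subset class-balanced; scoring against a target-trained probe
keeps it target-relevant, which is what protects the downstream model from
negative transfer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data import FeatureMatrix


@dataclass
class ProbeClassifier:
    """Target-trained probe: standardizer + one-vs-one SVM with probabilities."""

    pipeline: Pipeline
    classes: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-class probabilities, columns ordered as ``self.classes``."""
        return self.pipeline.predict_proba(np.asarray(X, dtype=float))


@dataclass
class InstanceScores:
    """Per-source-row informativeness scores in [0, 1]."""

    w: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 1:
            raise ValueError("scores must be a 1-D vector")
        if np.any((self.w < -1e-12) | (self.w > 1 + 1e-12)):
            raise ValueError("scores must lie in [0, 1]")


@dataclass
class SelectedInstances:
    """The per-class top-k source subset with provenance.

    Rows are grouped by class (ascending label); within a class they are
    sorted by descending score with ties broken by original source order.
    """

    X: np.ndarray
    y: np.ndarray
    k: int
    scores: np.ndarray
    origin_subject: np.ndarray
    origin_index: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def per_class_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.y, return_counts=True)
        return {int(c): int(n) for c, n in zip(labels, counts)}

    def per_subject_counts(self) -> dict[str, int]:
        subj, counts = np.unique(self.origin_subject, return_counts=True)
        return {str(s): int(n) for s, n in zip(subj, counts)}

    def report(self) -> dict:
        """JSON-ready provenance summary of the selection."""
        return {
            "k": int(self.k),
            "n_selected": int(self.n),
            "per_class_counts": self.per_class_counts(),
            "per_subject_counts": self.per_subject_counts(),
            "score_summary": {
                "min": float(self.scores.min()) if self.n else None,
                "median": float(np.median(self.scores)) if self.n else None,
                "max": float(self.scores.max()) if self.n else None,
            },
        }


def train_probe(
    T_L: FeatureMatrix | np.ndarray,
    y: np.ndarray | None = None,
    *,
    kernel: str = "linear",
    C: float = 1.0,
    seed: int = 0,
    n_classes: int | None = None,
) -> ProbeClassifier:
    """Train the probe classifier C0 on labeled target calibration data.

    Features are z-scored (scaler fitted on the calibration set and stored
    in the model); the SVM is one-vs-one with Platt-calibrated probability
    outputs, deterministic for a fixed ``seed``.
    """
    if isinstance(T_L, FeatureMatrix):
        X, y = T_L.X, T_L.y if y is None else y
    else:
        X = np.asarray(T_L, dtype=float)
    if y is None:
        raise ValueError("labels are required to train the probe")
    y = np.asarray(y, dtype=int)
    present = np.unique(y)
    if n_classes is not None:
        missing = sorted(set(range(1, n_classes + 1)) - set(present.tolist()))
        if missing:
            raise ValueError(f"calibration data is missing class(es) {missing}")
    if len(present) < 2:
        raise ValueError(
            f"probe training needs at least 2 classes, got {present.tolist()}"
        )
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                SVC(
                    kernel=kernel,
                    C=C,
                    probability=True,
                    random_state=seed,
                ),
            ),
        ]
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*probability.*", category=FutureWarning)
        pipe.fit(X, y)
    return ProbeClassifier(pipeline=pipe, classes=pipe.classes_)


def score_instances(
    probe: ProbeClassifier,
    S_L: FeatureMatrix | np.ndarray,
    y_s: np.ndarray | None = None,
    mode: str = "true_label",
) -> InstanceScores:
    """Score every source sample by the probe's probability output.

    ``mode="true_label"`` (default): w_i is the probability C0 assigns to
    the sample's own label — agreement with the target subject's expression
    of that emotion. ``mode="max_prob"``: the maximum class probability,
    regardless of label.
    """
    if isinstance(S_L, FeatureMatrix):
        X, y_s = S_L.X, S_L.y if y_s is None else y_s
    else:
        X = np.asarray(S_L, dtype=float)
    n_fit = probe.pipeline.named_steps["scale"].mean_.shape[0]
    if X.shape[1] != n_fit:
        raise ValueError(f"feature dim {X.shape[1]} does not match probe dim {n_fit}")
    proba = probe.predict_proba(X)
    if mode == "true_label":
        if y_s is None:
            raise ValueError("true_label scoring requires source labels")
        y_s = np.asarray(y_s, dtype=int)
        col = np.searchsorted(probe.classes, y_s)
        if np.any(col >= len(probe.classes)) or np.any(probe.classes[col] != y_s):
            bad = sorted(set(y_s.tolist()) - set(probe.classes.tolist()))
            raise ValueError(f"source labels {bad} unknown to the probe")
        w = proba[np.arange(len(y_s)), col]
    elif mode == "max_prob":
        w = proba.max(axis=1)
    else:
        raise ValueError(f"unknown score mode {mode!r}")
    return InstanceScores(w=w, mode=mode)


def select_top_k(
    S_L: FeatureMatrix | np.ndarray,
    y_s: np.ndarray | None,
    scores: InstanceScores | np.ndarray,
    k: int,
    origin_subject: np.ndarray | None = None,
    origin_index: np.ndarray | None = None,
) -> SelectedInstances:
    """Keep the top-k highest scoring source samples per emotion category.

    Within each class, rows are sorted by descending score with a stable
    tie-break (original source order); the first ``min(k, class size)`` are
    kept. Classes are concatenated in ascending label order.
    """
    if isinstance(S_L, FeatureMatrix):
        X, y_s = S_L.X, S_L.y if y_s is None else y_s
    else:
        X = np.asarray(S_L, dtype=float)
    if y_s is None:
        raise ValueError("labels are required for per-class selection")
    y_s = np.asarray(y_s, dtype=int)
    w = scores.w if isinstance(scores, InstanceScores) else np.asarray(scores, float)
    if len(w) != len(y_s) or len(w) != X.shape[0]:
        raise ValueError("scores, labels and rows must align")
    if k < 1:
        raise ValueError("k must be >= 1")
    if origin_subject is None:
        origin_subject = np.full(X.shape[0], "", dtype=object)
    if origin_index is None:
        origin_index = np.arange(X.shape[0])

    keep: list[np.ndarray] = []
    for c in np.unique(y_s):
        idx = np.flatnonzero(y_s == c)
        # stable argsort of -w keeps original order among ties
        order = idx[np.argsort(-w[idx], kind="stable")]
        keep.append(order[: min(k, len(order))])
    sel = np.concatenate(keep) if keep else np.empty(0, dtype=int)
    return SelectedInstances(
        X=X[sel],
        y=y_s[sel],
        k=int(k),
        scores=w[sel],
        origin_subject=np.asarray(origin_subject, dtype=object)[sel],
        origin_index=np.asarray(origin_index)[sel],
    )
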