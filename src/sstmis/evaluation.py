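"""Leave-one-subject-out (LOSO) evaluation harness.

Each subject in turn is the target; all other subjects' sessions form the
source pool. The target's first sessions (whole sessions, until every
emotion class has appeared — exactly three for three-class data with
alternating stimuli) are the labeled calibration set T_L; the remainder is
the unlabeled test set T_U. Accuracy is the fraction of T_U rows correctly
labeled, reported per subject and as mean ± population std across subjects.
"""

from __future__ import annotations

import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from . import classify, instance_selection, sstm
from .config import RunConfig
from .data import CohortDataset, FeatureMatrix, SourcePool

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Outcome of one target subject's pipeline run."""

    subject: str
    mode: str
    n_calibration: int
    n_test: int
    n_correct: int
    confusion: np.ndarray  # n_c × n_c counts, rows = truth
    labels: np.ndarray  # class labels indexing the confusion matrix
    timings: dict[str, float] = field(default_factory=dict)
    selection_report: dict | None = None
    map_cond: float | None = None

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_test if self.n_test else float("nan")

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.accuracy


@dataclass
class LOSOResult:
    """Cohort-level LOSO summary: per-subject accuracies and pooled confusion."""

    per_subject: dict[str, float]  # subject -> accuracy in %
    confusion: np.ndarray
    labels: np.ndarray
    config: dict
    timings: dict[str, float] = field(default_factory=dict)

    @property
    def mean_pct(self) -> float:
        return float(np.mean(list(self.per_subject.values())))

    @property
    def std_pct(self) -> float:
        # population std, matching the "mean ± std across subjects" convention
        return float(np.std(list(self.per_subject.values())))

    def to_dict(self) -> dict:
        """JSON-ready summary. Timings are deliberately excluded so that
        result files are byte-identical across runs with the same seed."""
        counts = self.confusion
        row = counts.sum(axis=1, keepdims=True)
        pct = np.where(row > 0, 100.0 * counts / np.maximum(row, 1), 0.0)
        return {
            "schema_version": 1,
            "config": self.config,
            "per_subject_accuracy_pct": {
                k: round(v, 10) for k, v in sorted(self.per_subject.items())
            },
            "mean_accuracy_pct": round(self.mean_pct, 10),
            "std_accuracy_pct": round(self.std_pct, 10),
            "confusion_counts": counts.astype(int).tolist(),
            "confusion_row_pct": [[round(x, 6) for x in r] for r in pct],
            "confusion_labels": self.labels.astype(int).tolist(),
        }


def loso_split(ds: CohortDataset, target: str) -> tuple[SourcePool, FeatureMatrix]:
    """All other subjects' rows (with provenance) vs. the target subject."""
    target_fm = ds.get(target)  # raises KeyError for unknown subject
    Xs, ys, sess, subj, idx = [], [], [], [], []
    for sid, fm in ds:
        if sid == target:
            continue
        Xs.append(fm.X)
        ys.append(fm.y)
        sess.append(fm.session)
        subj.append(np.full(fm.n, sid, dtype=object))
        idx.append(np.arange(fm.n))
    pool_fm = FeatureMatrix(
        X=np.vstack(Xs),
        y=np.concatenate(ys),
        subject="",
        session=np.concatenate(sess),
        feature_names=ds.subjects[0][1].feature_names,
    )
    return (
        SourcePool(
            fm=pool_fm,
            row_subject=np.concatenate(subj),
            row_index=np.concatenate(idx),
        ),
        target_fm,
    )


def calibration_split(
    target: FeatureMatrix, classes: np.ndarray | None = None
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Whole-session calibration split of the target subject.

    Sessions are accumulated in order until every emotion class has
    appeared; for three-class data at least three sessions are taken (the
    fixed first-three-sessions rule for alternating three-class stimuli).
    The split never cuts inside a session. ``classes`` may pass the cohort
    label set explicitly; it defaults to the labels present in the target.
    Raises if some class never appears (including the degenerate
    all-sessions-one-class case, where no calibration is possible).
    """
    if target.y is None:
        raise ValueError("calibration split requires labels")
    if classes is None:
        classes = set(target.classes.tolist())
        if len(classes) < 2:
            raise ValueError(
                f"subject {target.subject!r} has a single emotion class; "
                "other classes never appear, so no calibration split exists"
            )
    else:
        classes = set(np.asarray(classes).tolist())
    min_sessions = 3 if len(classes) == 3 else 1
    order = target.session_ids()
    seen: set[int] = set()
    taken: list[int] = []
    for s in order:
        taken.append(int(s))
        seen |= set(target.y[target.session == s].tolist())
        if seen == classes and len(taken) >= min_sessions:
            break
    if seen != classes:
        missing = sorted(classes - seen)
        raise ValueError(
            f"class(es) {missing} never appear in subject {target.subject!r} sessions"
        )
    mask = np.isin(target.session, taken)
    return target.subset(mask), target.subset(~mask)


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, labels: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Confusion counts (rows = truth) and row-normalized percentages."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} truth vs {y_pred.shape} predictions"
        )
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    counts = _sk_confusion(y_true, y_pred, labels=labels)
    row = counts.sum(axis=1, keepdims=True)
    pct = np.where(row > 0, 100.0 * counts / np.maximum(row, 1), 0.0)
    return counts, pct


@contextmanager
def _stage(timings: dict[str, float], name: str):
    t0 = time.perf_counter()
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    finally:
        dt = time.perf_counter() - t0
        timings[name] = timings.get(name, 0.0) + dt
        logger.info("stage %-16s %8.3f s", name, dt)


def run_pipeline(
    ds: CohortDataset, target: str, config: RunConfig | None = None
) -> PipelineResult:
    """Execute the pipeline for one target subject.

    ``full``: probe → score → select top-k → class statistics → Gaussian
    map → closed-form affine solve → inverse-map T_U → train C → predict.
    ``sstm``: same without selection (the whole pool is used).
    ``instance-sel``: selection only; C is trained on the selected
    instances (+ raw T_L) and applied to raw T_U.
    ``baseline``: no selection, no mapping — the no-adaptation control.
    """
    config = (config or RunConfig()).validate()
    timings: dict[str, float] = {}
    labels_all = ds.classes

    with _stage(timings, "loso_split"):
        pool, target_fm = loso_split(ds, target)
    with _stage(timings, "calibration_split"):
        T_L, T_U = calibration_split(target_fm, classes=labels_all)
        if T_U.n == 0:
            raise ValueError("no test rows left after calibration split")

    do_select = config.mode in ("full", "instance-sel") and config.k is not None
    do_map = config.mode in ("full", "sstm")

    sel_report = None
    if do_select:
        with _stage(timings, "probe"):
            probe = instance_selection.train_probe(
                T_L,
                kernel=config.kernel,
                C=config.svm_c,
                seed=config.stage_seed("probe"),
                n_classes=len(labels_all),
            )
        with _stage(timings, "score"):
            scores = instance_selection.score_instances(
                probe, pool.fm, mode=config.score_mode
            )
        with _stage(timings, "select"):
            sel = instance_selection.select_top_k(
                pool.fm,
                None,
                scores,
                config.k,
                origin_subject=pool.row_subject,
                origin_index=pool.row_index,
            )
            sel_report = sel.report()
    else:
        sel = instance_selection.SelectedInstances(
            X=pool.fm.X,
            y=pool.fm.y,
            k=0,
            scores=np.ones(pool.fm.n),
            origin_subject=pool.row_subject,
            origin_index=pool.row_index,
        )

    map_cond = None
    if do_map:
        with _stage(timings, "style_map"):
            amap, stats, mapped = sstm.fit_style_map(
                sel,
                T_L,
                beta=config.beta,
                gamma=config.gamma,
                shrinkage=config.shrinkage,
                rho_mode=config.rho_mode,
                rho=config.rho,
                f_mode=config.f_mode,
            )
            map_cond = amap.cond
        with _stage(timings, "apply_inverse"):
            U_prime = sstm.apply_inverse(amap, T_U, cond_cap=config.cond_cap)
            TL_mapped = sstm.apply_inverse(amap, T_L, cond_cap=config.cond_cap)
    else:
        U_prime = T_U
        TL_mapped = T_L

    with _stage(timings, "train_classifier"):
        model = classify.train_emotion_model(
            sel,
            mapped_T_L=TL_mapped,
            mode=config.train_mode,
            kernel=config.kernel,
            C=config.svm_c,
            seed=config.stage_seed("classifier"),
        )
    with _stage(timings, "predict"):
        y_pred, _ = classify.predict(model, U_prime)

    counts, _ = confusion_matrix(T_U.y, y_pred, labels=labels_all)
    return PipelineResult(
        subject=target,
        mode=config.mode,
        n_calibration=T_L.n,
        n_test=T_U.n,
        n_correct=int((y_pred == T_U.y).sum()),
        confusion=counts,
        labels=labels_all,
        timings=timings,
        selection_report=sel_report,
        map_cond=map_cond,
    )


def run_loso(ds: CohortDataset, config: RunConfig | None = None) -> LOSOResult:
    """Run the pipeline with every subject as the target once."""
    config = (config or RunConfig()).validate()
    per_subject: dict[str, float] = {}
    total_conf = None
    timings: dict[str, float] = {}
    for sid in ds.ids:
        res = run_pipeline(ds, sid, config)
        per_subject[sid] = res.accuracy_pct
        total_conf = res.confusion if total_conf is None else total_conf + res.confusion
        for k, v in res.timings.items():
            timings[k] = timings.get(k, 0.0) + v
        logger.info("subject %-6s accuracy %6.2f%%", sid, res.accuracy_pct)
    return LOSOResult(
        per_subject=per_subject,
        confusion=total_conf,
        labels=ds.classes,
        config=config.to_dict(),
        timings=timings,
    )


def sweep_k(
    ds: CohortDataset,
    target: str,
    k_grid: list[int | None],
    config: RunConfig | None = None,
) -> list[dict]:
    """Accuracy/time per k for one target subject.

    The probe and the source scores do not depend on ``k`` (all stage seeds
    derive from the run seed), so every grid point sees identical scores
    and differs only in how many instances are kept.
    """
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    config = (config or RunConfig()).validate()
    rows = []
    for k in k_grid:
        cfg = RunConfig(**{**config.to_dict(), "k": k})
        t0 = time.perf_counter()
        res = run_pipeline(ds, target, cfg)
        rows.append(
            {
                "k": None if k is None else int(k),
                "accuracy_pct": res.accuracy_pct,
                "time_s": time.perf_counter() - t0,
                "n_selected": None if res.selection_report is None
                else res.selection_report["n_selected"],
            }
        )
    return rows
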