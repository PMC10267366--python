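"""File formats: feature tables, cohort manifests, results, SEED-style .mat.

Text features are CSV with a mandatory header (``subject, session, label``
then one column per feature); the binary container is a compressed ``.npz``
keyed ``{X, y, session, meta}``. A YAML manifest lists the per-subject
files of a cohort. Results are JSON with sorted keys so identical runs
produce byte-identical files.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import CohortDataset, FeatureMatrix

META_COLS = ("subject", "session", "label")


def write_features_csv(fm: FeatureMatrix, path: str | Path) -> None:
    names = fm.feature_names or [f"f{i + 1}" for i in range(fm.m)]
    df = pd.DataFrame(fm.X, columns=names)
    df.insert(0, "label", fm.y if fm.y is not None else np.full(fm.n, -1))
    df.insert(0, "session", fm.session)
    df.insert(0, "subject", fm.subject)
    df.to_csv(path, index=False, float_format="%.12g")


def read_features_csv(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return FeatureMatrix(X=np.empty((0, 0)))
    missing = [c for c in META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    feat_cols = [c for c in df.columns if c not in META_COLS]
    try:
        X = df[feat_cols].to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric feature cell ({exc})") from exc
    y = df["label"].to_numpy()
    y = None if len(y) and (y < 0).all() else y.astype(int) if len(y) else None
    subject = str(df["subject"].iloc[0]) if len(df) else ""
    return FeatureMatrix(
        X=X,
        y=y,
        subject=subject,
        session=df["session"].to_numpy(dtype=int),
        feature_names=feat_cols,
    )


def write_features_npz(fm: FeatureMatrix, path: str | Path) -> None:
    meta = json.dumps(
        {"subject": fm.subject, "feature_names": fm.feature_names}, sort_keys=True
    )
    np.savez_compressed(
        path,
        X=fm.X,
        y=fm.y if fm.y is not None else np.full(fm.n, -1),
        session=fm.session,
        meta=np.array(meta),
    )


def read_features_npz(path: str | Path) -> FeatureMatrix:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        y = z["y"]
        return FeatureMatrix(
            X=z["X"],
            y=None if len(y) and (y < 0).all() else y if len(y) else None,
            subject=meta.get("subject", ""),
            session=z["session"],
            feature_names=meta.get("feature_names"),
        )


def read_feature_file(path: str | Path) -> FeatureMatrix:
    """Dispatch on extension: ``.csv`` text or ``.npz`` binary container."""
    path = Path(path)
    if path.suffix == ".npz":
        return read_features_npz(path)
    return read_features_csv(path)


def read_mat_subject(
    path: str | Path,
    key_pattern: str = r"de_LDS(\d+)$",
    labels: list[int] | None = None,
) -> FeatureMatrix:
    """Load a SEED-style per-subject MATLAB container of DE features.

    Each key matching ``key_pattern`` (with the trial number as group 1)
    holds one trial's array, shape ``channels × windows × bands``; windows
    become rows with channel-major feature order and the trial number
    becomes the session index. ``labels`` optionally gives the per-trial
    emotion labels in trial order.
    """
    from scipy.io import loadmat

    data = loadmat(str(path))
    hits: list[tuple[int, str]] = []
    for key in data:
        mobj = re.search(key_pattern, key)
        if mobj:
            hits.append((int(mobj.group(1)), key))
    if not hits:
        found = sorted(k for k in data if not k.startswith("__"))
        raise ValueError(
            f"{path}: no keys match {key_pattern!r}; found {found}"
        )
    hits.sort()
    rows, sess, ys = [], [], []
    for order, (trial, key) in enumerate(hits):
        arr = np.asarray(data[key], dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"{path}:{key}: expected 3-D channels×windows×bands")
        ch, win, nb = arr.shape
        if win == 0:
            import warnings

            warnings.warn(f"{path}:{key}: empty trial skipped", RuntimeWarning)
            continue
        rows.append(arr.transpose(1, 0, 2).reshape(win, ch * nb))
        sess.append(np.full(win, trial, dtype=int))
        if labels is not None:
            ys.append(np.full(win, int(labels[order]), dtype=int))
    X = np.vstack(rows)
    return FeatureMatrix(
        X=X,
        y=np.concatenate(ys) if ys else None,
        subject=Path(path).stem,
        session=np.concatenate(sess),
    )


def save_cohort(
    ds: CohortDataset, out_dir: str | Path, fmt: str = "csv"
) -> Path:
    """Write per-subject feature files plus a manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for sid, fm in ds:
        fname = f"{sid}.{fmt}"
        if fmt == "csv":
            write_features_csv(fm, out / fname)
        elif fmt == "npz":
            write_features_npz(fm, out / fname)
        else:
            raise ValueError(f"unknown cohort format {fmt!r}")
        entries.append({"id": sid, "path": fname})
    manifest = {"schema_version": 1, "subjects": entries}
    mpath = out / "cohort.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return mpath


def load_cohort(manifest_path: str | Path) -> CohortDataset:
    """Load a cohort from its YAML manifest (paths relative to the manifest)."""
    mpath = Path(manifest_path)
    with open(mpath) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "subjects" not in manifest:
        raise ValueError(f"{mpath}: manifest must contain a 'subjects' list")
    subjects = []
    for entry in manifest["subjects"]:
        fm = read_feature_file(mpath.parent / entry["path"])
        fm.subject = str(entry["id"])
        subjects.append((str(entry["id"]), fm))
    return CohortDataset(subjects=subjects)


def write_json(payload: dict, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=2)
        fh.write("\n")
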