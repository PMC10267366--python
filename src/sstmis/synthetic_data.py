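"""Synthetic multi-subject cohorts with controllable subject "style".

Emulates the statistical structure the style-transfer pipeline assumes:
per-class Gaussian clusters in DE-feature space, distorted per subject by
an invertible affine style transform ``x -> A_s x + b_s`` plus measurement
noise, organized into contiguous same-label sessions with alternating class
order (adjacent sessions never share a label, mirroring how emotion-elicit
stimuli are presented). Optionally emits band-limited raw EEG whose
per-band power differs by class, for end-to-end tests of DE extraction.

What it does *not* emulate: non-Gaussian/heavy-tailed features, temporal
autocorrelation within a session, electrode artifacts, or non-affine
subject differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .data import BandSet, CohortDataset, FeatureMatrix, RawRecording
from . import de_features


@dataclass
class SyntheticCohortSpec:
    """Full generative description of a cohort.

    Defaults are the desk-scale study conditions: 6 subjects, 3 emotion
    classes, 10-D features, 12 sessions of 60 samples per subject
    (4,320 samples total), unit within-class covariance, and style severity
    (rotations ~1.2 rad, ±30% log-scales, shifts of norm ~5 against
    class-mean coordinates of sd 1.2) strong enough that a pooled
    source-trained classifier degrades visibly on an unseen subject —
    the cross-subject heterogeneity regime the method exists for.
    """

    n_subjects: int = 6
    n_classes: int = 3
    m: int = 10
    class_means: np.ndarray | None = None  # n_classes × m; drawn if None
    class_mean_sd: float = 1.2  # sd of drawn class-mean coordinates
    class_cov: float | np.ndarray = 1.0  # scalar isotropic or full m × m
    rotation_scale: float = 1.2  # sd of the style rotation angle (radians)
    log_scale_sd: float = 0.3  # sd of per-axis log-scales
    shift_sd: float = 5.0  # E||b_s|| of the style shift
    sessions_per_class: int = 4
    samples_per_session: int = 60
    noise_sd: float = 0.3  # iid measurement noise on emitted features
    seed: int = 0

    def validate(self) -> None:
        problems = []
        for name in ("n_subjects", "n_classes", "m", "sessions_per_class",
                     "samples_per_session"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1")
        if self.n_classes < 2:
            problems.append("n_classes must be >= 2")
        for name in ("class_mean_sd", "rotation_scale", "log_scale_sd",
                     "shift_sd", "noise_sd"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if self.class_means is not None:
            cm = np.asarray(self.class_means)
            if cm.shape != (self.n_classes, self.m):
                problems.append("class_means must be n_classes × m")
            elif len(np.unique(cm, axis=0)) != self.n_classes:
                problems.append("class_means must be pairwise distinct")
        if np.ndim(self.class_cov) == 2:
            cc = np.asarray(self.class_cov)
            if cc.shape != (self.m, self.m):
                problems.append("class_cov must be scalar or m × m")
        elif np.ndim(self.class_cov) == 0 and float(self.class_cov) <= 0:
            problems.append("scalar class_cov must be positive")
        if problems:
            raise ValueError("invalid cohort spec: " + "; ".join(problems))

    def cov_matrix(self) -> np.ndarray:
        if np.ndim(self.class_cov) == 0:
            return float(self.class_cov) * np.eye(self.m)
        return np.asarray(self.class_cov, dtype=float)


@dataclass
class GroundTruth:
    """Generative truth aligned with an emitted cohort."""

    class_means: np.ndarray  # n_classes × m (pre-style)
    styles: dict[str, tuple[np.ndarray, np.ndarray]]  # subject -> (A_s, b_s)
    latent: dict[str, np.ndarray] = field(default_factory=dict)  # pre-style samples
    labels: dict[str, np.ndarray] = field(default_factory=dict)


def _session_label_order(n_classes: int, sessions_per_class: int) -> list[int]:
    # round-robin: adjacent sessions always differ in label
    return [1 + (i % n_classes) for i in range(n_classes * sessions_per_class)]


def _random_style(
    rng: np.random.Generator, spec: SyntheticCohortSpec
) -> tuple[np.ndarray, np.ndarray]:
    m = spec.m
    G = rng.standard_normal((m, m))
    K = G - G.T
    nrm = np.linalg.norm(K, 2)
    if nrm > 0:
        K /= nrm
    theta = rng.normal(0.0, spec.rotation_scale)
    R = expm(theta * K)
    delta = rng.normal(0.0, spec.log_scale_sd, size=m)
    A = R @ np.diag(np.exp(delta))
    b = rng.standard_normal(m)
    b *= spec.shift_sd / np.sqrt(m)
    return A, b


def make_cohort(spec: SyntheticCohortSpec) -> tuple[CohortDataset, GroundTruth]:
    """Generate a styled multi-subject cohort, reproducibly from the seed.

    Subject ``s`` draws latent class-c samples ``x ~ N(mu_c, Sigma)`` and
    emits ``A_s x + b_s + eps`` with ``eps ~ N(0, noise_sd^2 I)``. Sessions
    are contiguous same-label blocks in alternating class order.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if spec.class_means is None:
        means = rng.normal(0.0, spec.class_mean_sd, size=(spec.n_classes, spec.m))
    else:
        means = np.asarray(spec.class_means, dtype=float)
    cov = spec.cov_matrix()
    cov_chol = np.linalg.cholesky(cov)
    order = _session_label_order(spec.n_classes, spec.sessions_per_class)

    subjects: list[tuple[str, FeatureMatrix]] = []
    truth = GroundTruth(class_means=means, styles={})
    for s in range(spec.n_subjects):
        sid = f"S{s + 1:02d}"
        A_s, b_s = _random_style(rng, spec)
        lat_blocks, y_blocks, sess_blocks = [], [], []
        for sess_idx, c in enumerate(order, start=1):
            z = rng.standard_normal((spec.samples_per_session, spec.m))
            x = means[c - 1] + z @ cov_chol.T
            lat_blocks.append(x)
            y_blocks.append(np.full(spec.samples_per_session, c, dtype=int))
            sess_blocks.append(np.full(spec.samples_per_session, sess_idx, dtype=int))
        latent = np.vstack(lat_blocks)
        eps = rng.normal(0.0, spec.noise_sd, size=latent.shape)
        emitted = latent @ A_s.T + b_s + eps
        y = np.concatenate(y_blocks)
        fm = FeatureMatrix(
            X=emitted, y=y, subject=sid, session=np.concatenate(sess_blocks)
        )
        subjects.append((sid, fm))
        truth.styles[sid] = (A_s, b_s)
        truth.latent[sid] = latent
        truth.labels[sid] = y
    return CohortDataset(subjects=subjects), truth


def make_raw_cohort(
    band_power_by_class: np.ndarray,
    bands: BandSet | None = None,
    n_subjects: int = 2,
    sessions_per_class: int = 2,
    segments_per_session: int = 20,
    n_channels: int = 4,
    srate: float = 256.0,
    noise_floor_sd: float = 0.05,
    seed: int = 0,
) -> dict[str, list[tuple[int, int, RawRecording]]]:
    """Band-limited raw EEG whose per-band power depends on the class.

    Each 1-s session segment is a sum over bands of band-pass-filtered
    Gaussian noise scaled to variance ``band_power_by_class[class-1, band]``,
    plus a broadband noise floor (which must be positive — a zero floor
    would make out-of-band variance identically zero and DE undefined).

    Returns ``{subject: [(session_index, label, RawRecording), ...]}`` where
    each recording holds one session's concatenated segments.
    """
    if bands is None:
        bands = BandSet.default5()
    power = np.asarray(band_power_by_class, dtype=float)
    n_classes = power.shape[0]
    if power.shape != (n_classes, len(bands)):
        raise ValueError("band_power_by_class must be n_classes × n_bands")
    if np.any(power <= 0):
        raise ValueError("band powers must be positive")
    if noise_floor_sd <= 0:
        raise ValueError("noise_floor_sd must be positive")
    bands.validate_against_srate(srate)

    rng = np.random.default_rng(seed)
    win = int(round(srate))
    order = _session_label_order(n_classes, sessions_per_class)
    sos_by_band = [
        de_features._bandpass_sos(b.low, b.high, srate) for b in bands
    ]

    out: dict[str, list[tuple[int, int, RawRecording]]] = {}
    for s in range(n_subjects):
        sid = f"S{s + 1:02d}"
        sessions = []
        for sess_idx, c in enumerate(order, start=1):
            n_samp = segments_per_session * win
            sig = rng.normal(0.0, noise_floor_sd, size=(n_channels, n_samp))
            for j, sos in enumerate(sos_by_band):
                raw = rng.standard_normal((n_channels, n_samp))
                band = de_features._filtfilt_sos(sos, raw)
                std = band.std(axis=-1, keepdims=True)
                std[std == 0] = 1.0
                sig += band / std * np.sqrt(power[c - 1, j])
            sessions.append((sess_idx, c, RawRecording(sig, srate)))
        out[sid] = sessions
    return out


def extract_raw_cohort_features(
    raw_cohort: dict[str, list[tuple[int, int, RawRecording]]],
    bands: BandSet | None = None,
    window_s: float = 1.0,
) -> CohortDataset:
    """DE-extract every session of a raw cohort into a CohortDataset."""
    if bands is None:
        bands = BandSet.default5()
    subjects = []
    for sid, sessions in raw_cohort.items():
        fms = [
            de_features.extract_de_features(
                rec, bands, window_s, subject=sid, session=sess_idx, label=label
            )
            for sess_idx, label, rec in sessions
        ]
        X = np.vstack([f.X for f in fms])
        y = np.concatenate([f.y for f in fms])
        sess = np.concatenate([f.session for f in fms])
        subjects.append(
            (sid, FeatureMatrix(X=X, y=y, subject=sid, session=sess,
                                feature_names=fms[0].feature_names))
        )
    return CohortDataset(subjects=subjects)
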