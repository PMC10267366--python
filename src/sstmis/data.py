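"""Core data containers shared by every pipeline stage.

The universal currency between stages is the :class:`FeatureMatrix` — an
``n × m`` matrix of differential-entropy (DE) features with integer emotion
labels and whole-session block structure. Raw multichannel EEG enters the
pipeline as a :class:`RawRecording`; a :class:`BandSet` names the frequency
bands over which DE is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np


class Band(NamedTuple):
    """A named frequency band in Hz."""

    name: str
    low: float
    high: float


class BandSet:
    """Ordered set of frequency bands.

    Feature vectors are laid out channel-major: for channel ``i`` and band
    ``j`` the feature index is ``i * len(bands) + j``.
    """

    def __init__(self, bands: Sequence[tuple[str, float, float]]):
        if not bands:
            raise ValueError("BandSet requires at least one band")
        self.bands = [Band(str(n), float(lo), float(hi)) for n, lo, hi in bands]
        for b in self.bands:
            if not (0 < b.low < b.high):
                raise ValueError(f"invalid band {b!r}: need 0 < low < high")

    @classmethod
    def default5(cls) -> "BandSet":
        """The five conventional EEG bands (delta through gamma)."""
        return cls(
            [
                ("delta", 1.0, 4.0),
                ("theta", 4.0, 8.0),
                ("alpha", 8.0, 14.0),
                ("beta", 14.0, 31.0),
                ("gamma", 31.0, 50.0),
            ]
        )

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    def validate_against_srate(self, srate: float) -> None:
        nyq = srate / 2.0
        for b in self.bands:
            if b.high > nyq:
                raise ValueError(
                    f"band {b.name} ({b.low}-{b.high} Hz) exceeds Nyquist "
                    f"frequency {nyq} Hz at srate={srate}"
                )

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self) -> Iterator[Band]:
        return iter(self.bands)

    def __getitem__(self, i: int) -> Band:
        return self.bands[i]

    def __repr__(self) -> str:
        inner = ", ".join(f"{b.name}:{b.low}-{b.high}" for b in self.bands)
        return f"BandSet([{inner}])"


@dataclass
class RawRecording:
    """Multichannel raw EEG: ``signal`` is channels × samples in microvolts."""

    signal: np.ndarray
    srate: float
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels × samples array")
        if self.signal.shape[0] < 1:
            raise ValueError("need at least one channel")
        if not self.srate > 0:
            raise ValueError("srate must be positive")
        if self.channel_names is None:
            self.channel_names = [f"ch{i + 1:02d}" for i in range(self.n_channels)]
        elif len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length does not match signal rows")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.srate


@dataclass
class FeatureMatrix:
    """``n × m`` feature matrix with optional labels and session structure.

    Parameters
    ----------
    X
        Feature rows, one per 1-s segment (or per sample for synthetic data).
    y
        Integer emotion labels in ``{1..n_c}``; ``None`` for unlabeled data.
    subject
        Identifier of the subject the rows belong to ("" for pooled data).
    session
        Per-row session index; a session is a contiguous block of rows
        recorded under one stimulus and sharing one label. Defaults to a
        single session 1.
    feature_names
        Optional column names (e.g. ``ch01_alpha``).
    """

    X: np.ndarray
    y: np.ndarray | None = None
    subject: str = ""
    session: np.ndarray | None = None
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (n samples × m features)")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite entries")
        n = self.X.shape[0]
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=int)
            if self.y.shape != (n,):
                raise ValueError(f"y has length {self.y.shape}, expected ({n},)")
        if self.session is None:
            self.session = np.ones(n, dtype=int)
        else:
            self.session = np.asarray(self.session, dtype=int)
            if self.session.shape != (n,):
                raise ValueError("session must have one entry per row")
        if self.feature_names is not None and len(self.feature_names) != self.m:
            raise ValueError("feature_names length does not match m")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        if self.y is None:
            raise ValueError("FeatureMatrix is unlabeled")
        return np.unique(self.y)

    def subset(self, mask: np.ndarray, subject: str | None = None) -> "FeatureMatrix":
        """Row subset preserving labels/session alignment."""
        mask = np.asarray(mask)
        return FeatureMatrix(
            X=self.X[mask],
            y=None if self.y is None else self.y[mask],
            subject=self.subject if subject is None else subject,
            session=self.session[mask],
            feature_names=self.feature_names,
        )

    def session_ids(self) -> np.ndarray:
        """Session indices in order of first appearance."""
        _, first = np.unique(self.session, return_index=True)
        return self.session[np.sort(first)]


@dataclass
class SourcePool:
    """Concatenated source-domain rows with per-row provenance."""

    fm: FeatureMatrix
    row_subject: np.ndarray  # per-row source subject id (str)
    row_index: np.ndarray  # per-row index within the source subject

    def __post_init__(self) -> None:
        if len(self.row_subject) != self.fm.n or len(self.row_index) != self.fm.n:
            raise ValueError("provenance arrays must align with rows")


@dataclass
class CohortDataset:
    """A multi-subject cohort: list of ``(subject_id, FeatureMatrix)``.

    All subjects must share the feature dimension and the label set, and
    session indices must label contiguous blocks.
    """

    subjects: list[tuple[str, FeatureMatrix]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.subjects:
            return
        m0 = self.subjects[0][1].m
        labels0 = set(self.subjects[0][1].classes.tolist())
        for sid, fm in self.subjects:
            if fm.m != m0:
                raise ValueError(f"subject {sid} has m={fm.m}, expected {m0}")
            if fm.y is None:
                raise ValueError(f"subject {sid} has no labels")
            if set(fm.classes.tolist()) != labels0:
                raise ValueError(f"subject {sid} label set differs from cohort")
            # session indices must be contiguous blocks
            change = np.flatnonzero(np.diff(fm.session) != 0)
            seen = fm.session[np.concatenate(([0], change + 1))]
            if len(np.unique(seen)) != len(seen):
                raise ValueError(f"subject {sid} has non-contiguous sessions")

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.subjects]

    @property
    def m(self) -> int:
        return self.subjects[0][1].m

    @property
    def classes(self) -> np.ndarray:
        return self.subjects[0][1].classes

    def get(self, subject: str) -> FeatureMatrix:
        for sid, fm in self.subjects:
            if sid == subject:
                return fm
        raise KeyError(f"unknown subject {subject!r}; have {self.ids}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[tuple[str, FeatureMatrix]]:
        return iter(self.subjects)
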