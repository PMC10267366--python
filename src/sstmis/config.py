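"""Run configuration: every stage hyperparameter in one validated object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

from . import sstm

#: Pipeline ablation modes.
MODES = ("full", "sstm", "instance-sel", "baseline")


@dataclass
class RunConfig:
    """All tunable parameters of one pipeline run.

    ``k`` is the per-class number of selected source instances (``None``
    keeps the whole pool). ``mode`` selects the pipeline variant: ``full``
    (selection + style mapping), ``sstm`` (mapping only, k=all),
    ``instance-sel`` (selection only, no mapping), ``baseline`` (neither —
    the no-adaptation control). The defaults are the method's fixed
    hyperparameters: ``beta=0.2``, ``gamma=2``.
    """

    k: int | None = None
    score_mode: str = "true_label"
    beta: float = sstm.DEFAULT_BETA
    gamma: float = sstm.DEFAULT_GAMMA
    shrinkage: float = sstm.DEFAULT_SHRINKAGE
    rho_mode: str = "class_mean_distance"
    rho: float | None = None
    f_mode: str = "unit"
    kernel: str = "linear"
    svm_c: float = 1.0
    train_mode: str = "sel_plus_mapped_target"
    mode: str = "full"
    cond_cap: float = sstm.DEFAULT_COND_CAP
    seed: int = 0

    def validate(self) -> "RunConfig":
        problems = []
        if self.k is not None and self.k < 1:
            problems.append("k must be >= 1 or None (keep all)")
        if self.score_mode not in ("true_label", "max_prob"):
            problems.append(f"unknown score_mode {self.score_mode!r}")
        if self.beta < 0 or self.gamma < 0:
            problems.append("beta and gamma must be >= 0")
        if not 0 <= self.shrinkage <= 1:
            problems.append("shrinkage must lie in [0, 1]")
        if self.rho_mode not in ("class_mean_distance", "source_model", "fixed"):
            problems.append(f"unknown rho_mode {self.rho_mode!r}")
        if self.rho_mode == "fixed" and (self.rho is None or self.rho <= 0):
            problems.append("fixed rho_mode requires rho > 0")
        if self.f_mode not in ("unit", "gaussian"):
            problems.append(f"unknown f_mode {self.f_mode!r}")
        if self.kernel not in ("linear", "rbf"):
            problems.append(f"unknown kernel {self.kernel!r}")
        if self.svm_c <= 0:
            problems.append("svm_c must be > 0")
        if self.train_mode not in ("sel_only", "sel_plus_mapped_target"):
            problems.append(f"unknown train_mode {self.train_mode!r}")
        if self.mode not in MODES:
            problems.append(f"unknown mode {self.mode!r}; choose from {MODES}")
        if self.cond_cap <= 1:
            problems.append("cond_cap must be > 1")
        if not (0 <= int(self.seed) < 2**31):
            problems.append("seed must lie in [0, 2^31)")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        return cls(**d).validate()

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the run seed."""
        # simple polynomial rolling hash: stable across processes, < 2^31
        acc = int(self.seed)
        for ch in stage:
            acc = (acc * 1000003 + ord(ch)) % (2**31 - 1)
        return acc
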