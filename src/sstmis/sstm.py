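"""Simplified style transfer mapping (SSTM).

A new subject's DE features differ from the source pool by a subject-specific
"style". SSTM assumes class-conditional Gaussian features and learns a single
affine map for the subject in three steps:

1. Per-class Gaussian models ``(mu_c, Sigma_c)`` on the selected source
   instances, with shrinkage-regularized covariances.
2. Gaussian-model target points: each labeled calibration sample ``t`` with
   label ``c`` is mapped to ``o = mu_c + min(1, rho_c / d) * (t - mu_c)``,
   where ``d`` is the Mahalanobis distance of ``t`` to class ``c``. Samples
   already close to the class model are kept as-is; outliers are pulled
   toward the class mean.
3. A regularized weighted least-squares fit of the affine map ``A o + b ≈ t``
   in closed form,

       min_{A,b}  sum_i f_i ||A o_i + b - t_i||^2
                  + beta ||A - I||_F^2 + gamma ||b||^2,

   with fixed hyperparameters (default ``beta = 0.2``, ``gamma = 2``) rather
   than the per-iteration update schedule of the original STM — the
   simplification that makes the method fast enough for real-time use.

At test time the *inverse* map ``u' = A^{-1}(t - b)`` places unlabeled target
features in the source/Gaussian-model space, where a source-trained
classifier applies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .data import FeatureMatrix
from .instance_selection import SelectedInstances

#: Fixed regularization defaults.
DEFAULT_BETA = 0.2
DEFAULT_GAMMA = 2.0
#: Default shrinkage intensity for class covariances.
DEFAULT_SHRINKAGE = 0.1
#: Condition-number cap above which inverting the learned map is refused.
DEFAULT_COND_CAP = 1e10


@dataclass
class ClassStatistics:
    """Gaussian model of one emotion class: mean and shrunk covariance."""

    label: int
    mu: np.ndarray
    sigma: np.ndarray
    shrinkage: float
    _chol: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != (self.mu.size, self.mu.size):
            raise ValueError("sigma must be m × m")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        try:
            self._chol = linalg.cholesky(self.sigma, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError(
                f"covariance of class {self.label} is not positive definite; "
                "increase the shrinkage intensity"
            ) from exc

    def mahalanobis(self, t: np.ndarray) -> float | np.ndarray:
        """Mahalanobis distance(s) ``sqrt((t-mu)^T Sigma^{-1} (t-mu))``.

        Accepts a single vector or an ``n × m`` matrix of rows.
        """
        t = np.asarray(t, dtype=float)
        single = t.ndim == 1
        diff = np.atleast_2d(t) - self.mu
        if diff.shape[1] != self.mu.size:
            raise ValueError(
                f"dimension {diff.shape[1]} does not match statistics m={self.mu.size}"
            )
        z = linalg.solve_triangular(self._chol, diff.T, lower=True)
        d = np.sqrt(np.einsum("ij,ij->j", z, z))
        return float(d[0]) if single else d


@dataclass
class GaussianMappedSet:
    """Target points ``O`` aligned 1:1 with the calibration rows."""

    O: np.ndarray
    d: np.ndarray  # per-sample Mahalanobis distance to its own class
    rho: dict[int, float]  # per-class deviation control
    factor: np.ndarray  # the applied clamp factor min(1, rho_c/d_i)


@dataclass
class ConfidenceWeights:
    """Per-sample confidence of the (t, o) correspondence."""

    f: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if np.any(self.f <= 0):
            raise ValueError("confidence weights must be strictly positive")


@dataclass
class AffineMap:
    """The learned style map ``o -> A o + b`` and its inverse contract."""

    A: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be square")
        if self.b.shape != (self.A.shape[0],):
            raise ValueError("b must be a length-m vector")
        if not (np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.b))):
            raise ValueError("affine map has non-finite entries")

    @property
    def m(self) -> int:
        return self.A.shape[0]

    @property
    def cond(self) -> float:
        return float(np.linalg.cond(self.A))

    def forward(self, U: np.ndarray) -> np.ndarray:
        """Apply ``A u + b`` row-wise."""
        U = np.asarray(U, dtype=float)
        return U @ self.A.T + self.b

    def inverse(self, T: np.ndarray, cond_cap: float = DEFAULT_COND_CAP) -> np.ndarray:
        """Apply ``A^{-1}(t - b)`` row-wise via a linear solve."""
        c = self.cond
        if not np.isfinite(c) or c > cond_cap:
            raise ValueError(
                f"A is ill-conditioned (cond={c:.3g} > cap {cond_cap:.3g}); "
                "refit with a larger beta"
            )
        T = np.asarray(T, dtype=float)
        return np.linalg.solve(self.A, (T - self.b).T).T

    def to_json(self, **extra) -> str:
        payload = {
            "A": self.A.tolist(),
            "b": self.b.tolist(),
            "m": self.m,
            "cond": self.cond,
            **extra,
        }
        return json.dumps(payload, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AffineMap":
        payload = json.loads(text)
        return cls(A=np.array(payload["A"]), b=np.array(payload["b"]))


def class_statistics(
    sel: SelectedInstances | FeatureMatrix | np.ndarray,
    y: np.ndarray | None = None,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> dict[int, ClassStatistics]:
    """Per-class mean and shrinkage-regularized covariance.

    ``Sigma_c = (1 - lambda) * S + lambda * (tr(S)/m) * I`` where ``S`` is
    the per-class sample covariance (maximum-likelihood form, divisor n).
    Shrinkage toward the scaled identity keeps ``Sigma_c`` positive
    definite when the class has fewer instances than feature dimensions.
    """
    if isinstance(sel, SelectedInstances):
        X, y = sel.X, sel.y
    elif isinstance(sel, FeatureMatrix):
        X, y = sel.X, sel.y if y is None else y
    else:
        X = np.asarray(sel, dtype=float)
    if y is None:
        raise ValueError("labels are required for class statistics")
    y = np.asarray(y, dtype=int)
    if not 0 <= shrinkage <= 1:
        raise ValueError("shrinkage must lie in [0, 1]")
    m = X.shape[1]
    out: dict[int, ClassStatistics] = {}
    for c in np.unique(y):
        rows = X[y == c]
        if rows.shape[0] < 2:
            raise ValueError(f"class {c} has {rows.shape[0]} instance(s); need >= 2")
        mu = rows.mean(axis=0)
        S = np.cov(rows, rowvar=False, ddof=0)
        S = np.atleast_2d(S)
        sigma = (1.0 - shrinkage) * S + shrinkage * (np.trace(S) / m) * np.eye(m)
        out[int(c)] = ClassStatistics(
            label=int(c), mu=mu, sigma=sigma, shrinkage=shrinkage
        )
    return out


def mahalanobis(t: np.ndarray, stats: ClassStatistics) -> float | np.ndarray:
    """Mahalanobis distance of ``t`` to the class model (square-root form)."""
    return stats.mahalanobis(t)


def gaussian_map(
    T_L: FeatureMatrix | np.ndarray,
    y: np.ndarray | None = None,
    stats: dict[int, ClassStatistics] | None = None,
    rho_mode: str = "class_mean_distance",
    rho: float | None = None,
) -> GaussianMappedSet:
    """Map labeled calibration samples to Gaussian-model target points.

    ``o_i = mu_c + min(1, rho_c / d_i) * (t_i - mu_c)``: samples within
    Mahalanobis distance ``rho_c`` of their class mean are kept unchanged;
    more distant samples are shrunk toward the mean, landing on the
    ``rho_c`` ellipsoid.

    ``rho_mode="class_mean_distance"`` sets ``rho_c`` to the mean distance
    of the calibration class-c samples to ``mu_c`` (scale-adaptive: roughly
    half of each class is clamped). ``rho_mode="source_model"`` uses the
    expected distance of a sample drawn from the class model itself
    (``E d ≈ sqrt(m)`` for a Gaussian), so strongly styled subjects are
    pulled firmly toward the source model. ``rho_mode="fixed"`` uses the
    scalar ``rho`` for every class.
    """
    if isinstance(T_L, FeatureMatrix):
        X, y = T_L.X, T_L.y if y is None else y
    else:
        X = np.asarray(T_L, dtype=float)
    if y is None or stats is None:
        raise ValueError("labels and class statistics are required")
    y = np.asarray(y, dtype=int)
    missing = sorted(set(y.tolist()) - set(stats.keys()))
    if missing:
        raise ValueError(f"no class statistics for label(s) {missing}")

    n, m = X.shape
    d = np.empty(n)
    for c in np.unique(y):
        idx = y == c
        d[idx] = stats[int(c)].mahalanobis(X[idx])

    rho_by_class: dict[int, float] = {}
    for c in np.unique(y):
        ci = int(c)
        if rho_mode == "fixed":
            if rho is None or rho <= 0:
                raise ValueError("fixed rho_mode requires a positive rho")
            rho_by_class[ci] = float(rho)
        elif rho_mode == "class_mean_distance":
            rho_by_class[ci] = float(d[y == c].mean())
        elif rho_mode == "source_model":
            rho_by_class[ci] = float(np.sqrt(m))
        else:
            raise ValueError(f"unknown rho_mode {rho_mode!r}")

    rho_arr = np.array([rho_by_class[int(c)] for c in y])
    with np.errstate(divide="ignore"):
        factor = np.minimum(1.0, np.where(d > 0, rho_arr / np.maximum(d, 1e-300), 1.0))
    mu_arr = np.vstack([stats[int(c)].mu for c in y])
    O = mu_arr + factor[:, None] * (X - mu_arr)
    return GaussianMappedSet(O=O, d=d, rho=rho_by_class, factor=factor)


def confidence_weights(
    mapped: GaussianMappedSet | np.ndarray,
    mode: str = "unit",
    m: int | None = None,
) -> ConfidenceWeights:
    """Confidence ``f_i`` of each (t, o) correspondence.

    ``unit`` (default): ``f_i = 1`` — calibration labels are ground truth.
    ``gaussian``: ``f_i = exp(-d_i^2 / (2 m))`` rescaled to maximum 1, so
    samples far from their class model contribute less to the fit.
    """
    if isinstance(mapped, GaussianMappedSet):
        d = mapped.d
        m = mapped.O.shape[1]
    else:
        d = np.asarray(mapped, dtype=float)
        if mode == "gaussian" and m is None:
            raise ValueError("gaussian mode needs the feature dimension m")
    if mode == "unit":
        return ConfidenceWeights(f=np.ones_like(d), mode=mode)
    if mode == "gaussian":
        f = np.exp(-(d**2) / (2.0 * float(m)))
        return ConfidenceWeights(f=f / f.max(), mode=mode)
    raise ValueError(f"unknown confidence mode {mode!r}")


def solve_affine(
    O: np.ndarray,
    T: np.ndarray,
    f: ConfidenceWeights | np.ndarray | None = None,
    beta: float = DEFAULT_BETA,
    gamma: float = DEFAULT_GAMMA,
) -> AffineMap:
    """Closed-form minimizer of the regularized weighted least-squares fit.

    Solves ``min_{A,b} sum_i f_i ||A o_i + b - t_i||^2 + beta ||A - I||_F^2
    + gamma ||b||^2`` via its stationarity conditions:

        f_hat = sum_i f_i + gamma
        o_hat = sum_i f_i o_i,   t_hat = sum_i f_i t_i
        P = sum_i f_i o_i o_i^T - o_hat o_hat^T / f_hat + beta I
        Q = sum_i f_i t_i o_i^T - t_hat o_hat^T / f_hat + beta I
        A = Q P^{-1},   b = (t_hat - A o_hat) / f_hat

    ``P`` is symmetric positive definite for any ``beta > 0`` (and for
    ``beta = 0`` whenever the weighted o-scatter is full rank); the system
    is solved by Cholesky factorization, never by an explicit inverse.
    """
    O = np.asarray(O, dtype=float)
    T = np.asarray(T, dtype=float)
    if O.shape != T.shape or O.ndim != 2:
        raise ValueError("O and T must be n × m matrices of equal shape")
    n, m = O.shape
    if f is None:
        fv = np.ones(n)
    else:
        fv = f.f if isinstance(f, ConfidenceWeights) else np.asarray(f, dtype=float)
    if fv.shape != (n,):
        raise ValueError("f must have one weight per row")
    if np.any(fv <= 0):
        raise ValueError("confidence weights must be strictly positive")
    if beta < 0 or gamma < 0:
        raise ValueError("beta and gamma must be non-negative")

    f_hat = fv.sum() + gamma
    o_hat = fv @ O
    t_hat = fv @ T
    eye = np.eye(m)
    P = (O * fv[:, None]).T @ O - np.outer(o_hat, o_hat) / f_hat + beta * eye
    Q = (T * fv[:, None]).T @ O - np.outer(t_hat, o_hat) / f_hat + beta * eye
    P = 0.5 * (P + P.T)
    try:
        cho = linalg.cho_factor(P)
    except linalg.LinAlgError as exc:
        raise ValueError(
            f"P is not positive definite (cond={np.linalg.cond(P):.3g}); "
            "the o-points are degenerate — use beta > 0"
        ) from exc
    # A = Q P^{-1}  <=>  P A^T = Q^T (P symmetric)
    A = linalg.cho_solve(cho, Q.T).T
    b = (t_hat - A @ o_hat) / f_hat
    return AffineMap(A=A, b=b)


def sstm_objective(
    A: np.ndarray,
    b: np.ndarray,
    O: np.ndarray,
    T: np.ndarray,
    f: np.ndarray | None = None,
    beta: float = DEFAULT_BETA,
    gamma: float = DEFAULT_GAMMA,
) -> float:
    """The regularized weighted squared-error objective (for diagnostics)."""
    O = np.asarray(O, float)
    T = np.asarray(T, float)
    fv = np.ones(O.shape[0]) if f is None else np.asarray(f, float)
    resid = O @ np.asarray(A).T + np.asarray(b) - T
    fit = float(np.sum(fv * np.einsum("ij,ij->i", resid, resid)))
    reg = beta * float(np.sum((A - np.eye(O.shape[1])) ** 2))
    reg += gamma * float(np.sum(np.asarray(b) ** 2))
    return fit + reg


def fit_style_map(
    sel: SelectedInstances,
    T_L: FeatureMatrix,
    beta: float = DEFAULT_BETA,
    gamma: float = DEFAULT_GAMMA,
    shrinkage: float = DEFAULT_SHRINKAGE,
    rho_mode: str = "class_mean_distance",
    rho: float | None = None,
    f_mode: str = "unit",
) -> tuple[AffineMap, dict[int, ClassStatistics], GaussianMappedSet]:
    """Convenience wrapper: statistics → Gaussian map → closed-form solve."""
    stats = class_statistics(sel, shrinkage=shrinkage)
    mapped = gaussian_map(T_L, stats=stats, rho_mode=rho_mode, rho=rho)
    weights = confidence_weights(mapped, mode=f_mode)
    amap = solve_affine(mapped.O, T_L.X, weights, beta=beta, gamma=gamma)
    return amap, stats, mapped


def apply_inverse(
    amap: AffineMap,
    T_U: FeatureMatrix | np.ndarray,
    cond_cap: float = DEFAULT_COND_CAP,
) -> FeatureMatrix | np.ndarray:
    """Place target-domain rows in the source space: ``u' = A^{-1}(t - b)``."""
    if isinstance(T_U, FeatureMatrix):
        U = amap.inverse(T_U.X, cond_cap=cond_cap)
        return FeatureMatrix(
            X=U,
            y=T_U.y,
            subject=T_U.subject,
            session=T_U.session,
            feature_names=T_U.feature_names,
        )
    return amap.inverse(np.asarray(T_U, dtype=float), cond_cap=cond_cap)
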