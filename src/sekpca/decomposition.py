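"""Linear PCA on the feature correlation matrix, kernel PCA on centred Gram
matrices, and cumulative-variance-contribution (CVC) component selection.

PCA here follows the correlation-matrix convention: columns are standardized
(mean 0, unit SD with the N-1 divisor) and the eigendecomposition is taken of
the feature correlation matrix, so every channel enters with equal weight.

KPCA solves the dual eigenproblem ``K~ a = mu a`` on the double-centred Gram
matrix and normalizes each dual coefficient vector so the implicit
feature-space component has unit length (``mu * ||a||^2 = 1``). Out-of-sample
projection centres the test kernel rows with the *training* statistics, which
is what keeps a cross-validated pipeline leak-free.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import pairwise

from .errors import ConfigurationError
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "KernelSpec",
    "StandardizeStats",
    "KernelCenteringStats",
    "DecompositionResult",
    "standardize",
    "apply_standardize",
    "pca_fit",
    "pca_project",
    "cvc_select",
    "kernel_matrix",
    "center_kernel",
    "kpca_fit",
    "kpca_project",
]

_FAMILIES = {"linear", "polynomial", "rbf", "mlp"}


@dataclass(frozen=True)
class KernelSpec:
    """A kernel family plus its parameters.

    linear:      k(x, y) = x . y
    polynomial:  k(x, y) = (x . y + 1)^P              (P > 0, may be fractional)
    rbf:         k(x, y) = exp(-||x - y||^2 / delta^2)   [or unsquared distance
                 with squared=False]
    mlp:         k(x, y) = tanh(v (x . y) + c)        (not PSD in general)
    """

    family: str = "rbf"
    P: float | None = None
    delta: float | None = None
    v: float | None = None
    c: float | None = None
    squared: bool = True  # rbf exponent uses squared distance by default

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(f"unknown kernel family {self.family!r}")
        if self.family == "polynomial" and (self.P is None or self.P <= 0):
            raise ConfigurationError("polynomial kernel needs order P > 0")
        if self.family == "rbf" and (self.delta is None or self.delta <= 0):
            raise ConfigurationError("rbf kernel needs scale delta > 0")
        if self.family == "mlp" and (self.v is None or self.c is None):
            raise ConfigurationError("mlp kernel needs slope v and offset c")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "P": self.P,
            "delta": self.delta,
            "v": self.v,
            "c": self.c,
            "squared": self.squared,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(**d)


def _values(X: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ConfigurationError("expected a 2-D sample x feature matrix")
    if not np.all(np.isfinite(arr)):
        raise ConfigurationError("matrix contains non-finite entries")
    return arr


def kernel_matrix(
    X: FeatureMatrix | np.ndarray,
    Y: FeatureMatrix | np.ndarray,
    spec: KernelSpec,
) -> np.ndarray:
    """Gram matrix with entry (i, j) = k(x_i, y_j)."""
    x, y = _values(X), _values(Y)
    if x.shape[1] != y.shape[1]:
        raise ConfigurationError(
            f"feature-count mismatch: {x.shape[1]} vs {y.shape[1]}"
        )
    if spec.family == "linear":
        return pairwise.linear_kernel(x, y)
    if spec.family == "polynomial":
        base = pairwise.linear_kernel(x, y) + 1.0
        if spec.P != int(spec.P) and np.any(base < 0):
            raise ConfigurationError(
                "fractional polynomial order with negative (x.y + 1); "
                "kernel undefined for this data"
            )
        return base**spec.P
    if spec.family == "rbf":
        assert spec.delta is not None
        if spec.squared:
            return pairwise.rbf_kernel(x, y, gamma=1.0 / spec.delta**2)
        d = pairwise.euclidean_distances(x, y)
        return np.exp(-d / spec.delta**2)
    # mlp / sigmoid
    return pairwise.sigmoid_kernel(x, y, gamma=spec.v, coef0=spec.c)


@dataclass
class StandardizeStats:
    """Per-column training mean and SD (N-1 divisor) used to scale new rows."""

    mean: np.ndarray
    sd: np.ndarray


def standardize(
    X: FeatureMatrix | np.ndarray,
) -> tuple[np.ndarray, StandardizeStats]:
    """Column-wise z-scoring; errors name any zero-variance column."""
    x = _values(X)
    if x.shape[0] < 2:
        raise ConfigurationError("need at least 2 samples to standardize")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = (
            [X.feature_names[i] for i in dead]
            if isinstance(X, FeatureMatrix)
            else dead.tolist()
        )
        raise ConfigurationError(f"zero-variance column(s): {names}")
    return (x - mean) / sd, StandardizeStats(mean=mean, sd=sd)


def apply_standardize(X: FeatureMatrix | np.ndarray, stats: StandardizeStats) -> np.ndarray:
    return (_values(X) - stats.mean) / stats.sd


@dataclass
class KernelCenteringStats:
    """Training Gram column means and grand mean, for centring test rows."""

    col_means: np.ndarray
    grand_mean: float


def center_kernel(
    K: np.ndarray,
    training_stats: KernelCenteringStats | None = None,
) -> tuple[np.ndarray, KernelCenteringStats] | np.ndarray:
    """Double-centre a Gram matrix.

    Fit mode (square ``K``, no stats): returns ``(K~, stats)`` where
    ``K~ = K - 1K - K1 + 1K1`` with ``1`` the M x M matrix of 1/M entries;
    every row and column of ``K~`` sums to zero. Projection mode
    (rectangular test-vs-train ``K`` plus the stored training stats):
    returns the test rows centred with the *training* means.
    """
    K = np.asarray(K, dtype=float)
    if training_stats is None:
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ConfigurationError(
                "fit-mode centering needs a square Gram matrix "
                "(pass training_stats to centre test rows)"
            )
        col = K.mean(axis=0)
        grand = float(K.mean())
        centered = K - col[None, :] - K.mean(axis=1)[:, None] + grand
        return centered, KernelCenteringStats(col_means=col, grand_mean=grand)
    if K.shape[1] != training_stats.col_means.size:
        raise ConfigurationError("test Gram width does not match training size")
    row = K.mean(axis=1)[:, None]
    return K - training_stats.col_means[None, :] - row + training_stats.grand_mean


@dataclass
class DecompositionResult:
    """Fitted PCA or KPCA decomposition.

    ``eigenvalues`` are sorted non-increasing (for KPCA these are the
    eigenvalues mu of the centred Gram matrix, truncated to the retained
    non-negligible ones). ``components`` holds PCA loading vectors (columns,
    unit norm) or KPCA dual coefficients a (columns, normalized so
    mu * ||a||^2 = 1). ``contribution_rates`` are eigenvalue fractions over
    the retained spectrum. The centering state is everything needed to
    project unseen rows without re-fitting.
    """

    kind: str  # "pca" | "kpca"
    eigenvalues: np.ndarray
    components: np.ndarray
    contribution_rates: np.ndarray
    standardize_stats: StandardizeStats | None = None
    kernel_stats: KernelCenteringStats | None = None
    kernel_spec: KernelSpec | None = None
    train_X: np.ndarray | None = None  # rows the kernel must be evaluated against
    n_selected: int | None = None
    n_truncated_negative: int = 0

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size

    def select(self, threshold: float) -> int:
        self.n_selected = cvc_select(self.contribution_rates, threshold)
        return self.n_selected

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "eigenvalues": self.eigenvalues.tolist(),
            "components": self.components.tolist(),
            "contribution_rates": self.contribution_rates.tolist(),
            "n_selected": self.n_selected,
            "n_truncated_negative": self.n_truncated_negative,
        }
        if self.standardize_stats is not None:
            payload["standardize_stats"] = {
                "mean": self.standardize_stats.mean.tolist(),
                "sd": self.standardize_stats.sd.tolist(),
            }
        if self.kernel_stats is not None:
            payload["kernel_stats"] = {
                "col_means": self.kernel_stats.col_means.tolist(),
                "grand_mean": self.kernel_stats.grand_mean,
            }
        if self.kernel_spec is not None:
            payload["kernel_spec"] = self.kernel_spec.to_dict()
        if self.train_X is not None:
            payload["train_X"] = self.train_X.tolist()
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "DecompositionResult":
        d = json.loads(Path(path).read_text())
        return cls(
            kind=d["kind"],
            eigenvalues=np.asarray(d["eigenvalues"]),
            components=np.asarray(d["components"]),
            contribution_rates=np.asarray(d["contribution_rates"]),
            standardize_stats=(
                StandardizeStats(
                    mean=np.asarray(d["standardize_stats"]["mean"]),
                    sd=np.asarray(d["standardize_stats"]["sd"]),
                )
                if "standardize_stats" in d
                else None
            ),
            kernel_stats=(
                KernelCenteringStats(
                    col_means=np.asarray(d["kernel_stats"]["col_means"]),
                    grand_mean=d["kernel_stats"]["grand_mean"],
                )
                if "kernel_stats" in d
                else None
            ),
            kernel_spec=(
                KernelSpec.from_dict(d["kernel_spec"]) if "kernel_spec" in d else None
            ),
            train_X=np.asarray(d["train_X"]) if "train_X" in d else None,
            n_selected=d.get("n_selected"),
            n_truncated_negative=d.get("n_truncated_negative", 0),
        )


def _sign_fix(vectors: np.ndarray) -> np.ndarray:
    """Make the first nonzero entry of each column positive (reproducible signs)."""
    out = vectors.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            out[:, k] = -col
    return out


def pca_fit(X: FeatureMatrix | np.ndarray) -> DecompositionResult:
    """Eigendecomposition of the feature correlation matrix.

    Standardizes internally (the stored stats are reused by
    :func:`pca_project`); eigenvalues are sorted descending and loading
    vectors are unit-norm.
    """
    x = _values(X)
    y, stats = standardize(X)
    r = (y.T @ y) / (x.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(r)
    order = np.argsort(eigvals, kind="stable")[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = _sign_fix(eigvecs[:, order])
    total = eigvals.sum()
    rates = eigvals / total if total > 0 else eigvals
    return DecompositionResult(
        kind="pca",
        eigenvalues=eigvals,
        components=eigvecs,
        contribution_rates=rates,
        standardize_stats=stats,
    )


def pca_project(
    Xnew: FeatureMatrix | np.ndarray, fitted: DecompositionResult, k: int
) -> np.ndarray:
    """Scores of new rows on the first k principal components."""
    if fitted.kind != "pca":
        raise ConfigurationError("pca_project needs a PCA fit")
    if k > fitted.n_components:
        raise ConfigurationError(f"k={k} exceeds {fitted.n_components} components")
    assert fitted.standardize_stats is not None
    y = apply_standardize(Xnew, fitted.standardize_stats)
    return y @ fitted.components[:, :k]


def cvc_select(
    contribution_rates: Sequence[float] | np.ndarray, threshold: float
) -> int:
    """Smallest k whose cumulative contribution reaches the threshold.

    Rates must be non-negative and non-increasing. A 1e-12 epsilon guards
    against decimal rates whose float sum lands a hair under a round
    threshold. If the total never reaches the threshold, all components are
    returned with a warning.
    """
    rates = np.asarray(contribution_rates, dtype=float)
    if rates.size == 0:
        raise ConfigurationError("empty contribution-rate sequence")
    if not 0 < threshold <= 1:
        raise ConfigurationError("threshold must be in (0, 1]")
    if np.any(rates < 0) or np.any(np.diff(rates) > 1e-12):
        raise ConfigurationError("rates must be non-negative and non-increasing")
    cum = np.cumsum(rates)
    hits = np.flatnonzero(cum >= threshold - 1e-12)
    if hits.size == 0:
        warnings.warn(
            f"total contribution {cum[-1]:.4f} below threshold {threshold}; "
            "keeping all components",
            stacklevel=2,
        )
        return rates.size
    return int(hits[0]) + 1


def kpca_fit(
    X: FeatureMatrix | np.ndarray,
    spec: KernelSpec,
    standardize_input: bool = False,
    truncation_rtol: float = 1e-10,
) -> DecompositionResult:
    """Kernel PCA: eigendecomposition of the double-centred Gram matrix.

    Eigenvalues below ``max(mu) * truncation_rtol`` — including the negative
    ones an indefinite mlp kernel can produce — are truncated before
    contribution rates are computed; the truncated-negative count is logged.
    Dual coefficients are scaled so each feature-space component has unit
    length. Entropy features share a common nats scale, so the input is used
    raw by default; set ``standardize_input=True`` to z-score first.
    """
    x = _values(X)
    if x.shape[0] < 2:
        raise ConfigurationError("need at least 2 samples for kpca")
    std_stats = None
    if standardize_input:
        x, std_stats = standardize(x)
    K = kernel_matrix(x, x, spec)
    centered, kstats = center_kernel(K)
    eigvals, eigvecs = np.linalg.eigh(centered)
    order = np.argsort(eigvals, kind="stable")[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(eigvals.max(), 0.0) * truncation_rtol
    keep = eigvals > tol
    n_negative = int(np.count_nonzero(eigvals < 0))
    if n_negative:
        logger.info("truncated %d negative eigenvalue(s) (indefinite kernel)", n_negative)
    if not np.any(keep):
        raise ConfigurationError("degenerate kernel: no eigenvalue above tolerance")
    mu = eigvals[keep]
    coeffs = _sign_fix(eigvecs[:, keep]) / np.sqrt(mu)[None, :]
    rates = mu / mu.sum()
    return DecompositionResult(
        kind="kpca",
        eigenvalues=mu,
        components=coeffs,
        contribution_rates=rates,
        standardize_stats=std_stats,
        kernel_stats=kstats,
        kernel_spec=spec,
        train_X=x,
        n_truncated_negative=n_negative,
    )


def kpca_scores(fitted: DecompositionResult, k: int | None = None) -> np.ndarray:
    """Training-sample scores: mu_k * a_k for each retained component."""
    if fitted.kind != "kpca":
        raise ConfigurationError("kpca_scores needs a KPCA fit")
    k = k or fitted.n_components
    return fitted.components[:, :k] * fitted.eigenvalues[None, :k]


def kpca_project(
    Xnew: FeatureMatrix | np.ndarray,
    fitted: DecompositionResult,
    k: int | None = None,
) -> np.ndarray:
    """Project new rows: score_ik = sum_j a_jk * k~(x_j_train, x_i_new).

    Test kernel rows are centred with the training statistics.
    """
    if fitted.kind != "kpca":
        raise ConfigurationError("kpca_project needs a KPCA fit")
    k = k if k is not None else (fitted.n_selected or fitted.n_components)
    if k > fitted.n_components:
        raise ConfigurationError(
            f"k={k} exceeds the {fitted.n_components} retained components"
        )
    assert fitted.train_X is not None and fitted.kernel_spec is not None
    x = _values(Xnew)
    if fitted.standardize_stats is not None:
        x = apply_standardize(x, fitted.standardize_stats)
    K = kernel_matrix(x, fitted.train_X, fitted.kernel_spec)
    centered = center_kernel(K, fitted.kernel_stats)
    return centered @ fitted.components[:, :k]
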