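"""Per-epoch complexity estimators: sample entropy, fuzzy entropy, and a
pluggable combination-entropy slot, plus epoch-by-channel feature-matrix
construction.

Sample entropy follows the Richman–Moorman definition: with embedding
dimension ``m`` and tolerance ``r``, count ordered template pairs (i != j,
self-matches excluded) whose Chebyshev distance is below ``r`` at template
length ``m`` (count B) and at length ``m+1`` (count A), using the same
``N - m`` templates at both lengths, and return ``-ln(A/B)``. The tolerance
is ``r = r_factor * SD`` with the population (divide-by-N) standard
deviation of the epoch, so the statistic is invariant under affine amplitude
transforms of the signal.

Fuzzy entropy replaces the hard threshold with a graded exponential
membership ``exp(-(d^n)/r)`` evaluated on mean-centred templates, which makes
the statistic finite whenever the epoch has positive variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError, DegenerateEpochError, UndefinedEntropyError
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SignalEpoch",
    "EntropyParams",
    "sample_entropy",
    "fuzzy_entropy",
    "combination_entropy",
    "set_combination_estimator",
    "entropy_of",
    "epoch_feature_matrix",
]


@dataclass(frozen=True)
class SignalEpoch:
    """One channel's fixed-length window of samples at a known rate (Hz)."""

    samples: np.ndarray
    rate: float = 1.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ConfigurationError("an epoch must be a 1-D sample sequence")
        if not np.all(np.isfinite(samples)):
            raise ConfigurationError("epoch contains non-finite samples")
        object.__setattr__(self, "samples", samples)

    @property
    def n(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class EntropyParams:
    """Estimator settings. Defaults m=2, r_factor=0.25 (tolerance 0.25 SD)."""

    m: int = 2
    r_factor: float = 0.25
    estimator: str = "sample"
    fuzzy_gradient: int = 2  # exponent n of the exponential membership

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ConfigurationError("embedding dimension m must be >= 1")
        if self.r_factor <= 0:
            raise ConfigurationError("r_factor must be positive")
        if self.estimator not in {"sample", "fuzzy", "combination"}:
            raise ConfigurationError(f"unknown estimator {self.estimator!r}")
        if self.fuzzy_gradient < 1:
            raise ConfigurationError("fuzzy gradient n must be >= 1")


def _as_epoch(epoch: SignalEpoch | Sequence[float]) -> SignalEpoch:
    if isinstance(epoch, SignalEpoch):
        return epoch
    return SignalEpoch(np.asarray(epoch, dtype=float))


def _tolerance(x: np.ndarray, params: EntropyParams) -> float:
    # population SD by convention; a zero-variance epoch gives r = 0 and no
    # meaningful match counting, so it is rejected explicitly.
    sd = float(np.std(x))
    if sd == 0.0:
        raise DegenerateEpochError("epoch has zero standard deviation (r = 0)")
    return params.r_factor * sd


def _check_length(n: int, m: int) -> None:
    if n < m + 2:
        raise ConfigurationError(f"epoch length {n} too short for m={m} (need >= m+2)")


try:  # numba accelerates the O(N^2) counting loops ~10x; numpy path is the fallback
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        return wrap


@njit(cache=False)
def _sampen_counts_loop(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    t = x.size - m
    a = 0
    b = 0
    for i in range(t):
        for j in range(i + 1, t):
            d = 0.0
            for k in range(m):
                dk = abs(x[i + k] - x[j + k])
                if dk > d:
                    d = dk
                if d >= r:
                    break
            if d < r:
                b += 1
                dk = abs(x[i + m] - x[j + m])
                if dk > d:
                    d = dk
                if d < r:
                    a += 1
    return a, b


def _sampen_counts_numpy(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    t = x.size - m
    # d0[i, j] = |x[i] - x[j]|; template distances are running maxima of its
    # diagonals, so d_m and d_{m+1} come from elementwise maxima of slices.
    d0 = np.abs(x[:, None] - x[None, :])
    dm = d0[:t, :t]
    for k in range(1, m):
        dm = np.maximum(dm, d0[k : k + t, k : k + t])
    dm1 = np.maximum(dm, d0[m : m + t, m : m + t])
    off = ~np.eye(t, dtype=bool)
    b = int(np.count_nonzero((dm < r) & off))
    a = int(np.count_nonzero((dm1 < r) & off))
    return a, b


def sample_entropy_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int, int]:
    """Ordered-pair match counts (A at length m+1, B at length m, T templates).

    Both lengths use the same ``T = N - m`` templates so that every length-m
    template has a defined length-(m+1) extension; matching is strict
    (Chebyshev distance < r) and self-pairs are excluded.
    """
    x = np.asarray(x, dtype=float)
    if _HAVE_NUMBA:
        a, b = _sampen_counts_loop(x, m, r)
        return 2 * a, 2 * b, x.size - m  # unordered loop counts each pair once
    a, b = _sampen_counts_numpy(x, m, r)
    return a, b, x.size - m


def sample_entropy(
    epoch: SignalEpoch | Sequence[float], params: EntropyParams | None = None
) -> float:
    """Sample entropy of one epoch, in nats.

    Raises :class:`DegenerateEpochError` for a zero-variance epoch and
    :class:`UndefinedEntropyError` when either match count is zero (the
    log-ratio is undefined; never silently returned as a number).
    """
    params = params or EntropyParams()
    ep = _as_epoch(epoch)
    _check_length(ep.n, params.m)
    r = _tolerance(ep.samples, params)
    a, b, _ = sample_entropy_counts(ep.samples, params.m, r)
    if b == 0 or a == 0:
        raise UndefinedEntropyError(
            f"no template matches (A={a}, B={b}); entropy undefined for this epoch"
        )
    return float(-np.log(a / b))


def _fuzzy_phi_numpy(x: np.ndarray, t: int, length: int, n_grad: int, r: float) -> float:
    """Mean off-diagonal exponential membership over T mean-centred templates."""
    v = np.lib.stride_tricks.sliding_window_view(x, length)[:t]
    v = v - v.mean(axis=1, keepdims=True)
    d = np.zeros((t, t))
    for k in range(length):
        col = v[:, k]
        np.maximum(d, np.abs(col[:, None] - col[None, :]), out=d)
    mu = np.exp(-(d**n_grad) / r)
    total = mu.sum() - np.trace(mu)
    return float(total / (t * (t - 1)))


@njit(cache=False)
def _fuzzy_phi_loop(x: np.ndarray, t: int, length: int, n_grad: int, r: float) -> float:
    mu = np.empty(t)
    for i in range(t):
        s = 0.0
        for k in range(length):
            s += x[i + k]
        mu[i] = s / length
    total = 0.0
    for i in range(t):
        for j in range(i + 1, t):
            d = 0.0
            for k in range(length):
                dk = abs((x[i + k] - mu[i]) - (x[j + k] - mu[j]))
                if dk > d:
                    d = dk
            total += np.exp(-(d**n_grad) / r)
    return 2.0 * total / (t * (t - 1))


def _fuzzy_phi(x: np.ndarray, t: int, length: int, n_grad: int, r: float) -> float:
    if _HAVE_NUMBA:
        return _fuzzy_phi_loop(x, t, length, n_grad, r)
    return _fuzzy_phi_numpy(x, t, length, n_grad, r)


def fuzzy_entropy(
    epoch: SignalEpoch | Sequence[float], params: EntropyParams | None = None
) -> float:
    """Fuzzy entropy: graded-similarity analogue of sample entropy, in nats.

    Uses mean-centred templates of lengths m and m+1 (the same ``N - m``
    templates at both lengths) and membership ``exp(-(d^n)/r)``. Finite for
    any epoch with positive variance.
    """
    params = params or EntropyParams()
    ep = _as_epoch(epoch)
    _check_length(ep.n, params.m)
    r = _tolerance(ep.samples, params)
    t = ep.n - params.m
    phi_m = _fuzzy_phi(ep.samples, t, params.m, params.fuzzy_gradient, r)
    phi_m1 = _fuzzy_phi(ep.samples, t, params.m + 1, params.fuzzy_gradient, r)
    return float(np.log(phi_m) - np.log(phi_m1))


EntropyFn = Callable[[SignalEpoch, EntropyParams], float]


def _default_combination(epoch: SignalEpoch, params: EntropyParams) -> float:
    # Documented stand-in: the mean of sample and fuzzy entropy. Replace via
    # set_combination_estimator() with the composite estimator of your choice.
    return 0.5 * (sample_entropy(epoch, params) + fuzzy_entropy(epoch, params))


_COMBINATION_ESTIMATOR: EntropyFn | None = _default_combination


def set_combination_estimator(fn: EntropyFn | None) -> None:
    """Register the estimator backing :func:`combination_entropy`.

    ``None`` clears the slot (subsequent calls raise
    :class:`ConfigurationError`); the shipped default is the stand-in mean of
    sample and fuzzy entropy.
    """
    global _COMBINATION_ESTIMATOR
    _COMBINATION_ESTIMATOR = fn


def combination_entropy(
    epoch: SignalEpoch | Sequence[float], params: EntropyParams | None = None
) -> float:
    """Whatever estimator is registered under the ``combination`` slot."""
    params = params or EntropyParams()
    if _COMBINATION_ESTIMATOR is None:
        raise ConfigurationError(
            "no combination-entropy estimator registered; "
            "call set_combination_estimator() first"
        )
    ep = _as_epoch(epoch)
    _check_length(ep.n, params.m)
    _tolerance(ep.samples, params)  # degenerate epochs rejected for any estimator
    return float(_COMBINATION_ESTIMATOR(ep, params))


_DISPATCH: dict[str, Callable[..., float]] = {
    "sample": sample_entropy,
    "fuzzy": fuzzy_entropy,
    "combination": combination_entropy,
}


def entropy_of(
    epoch: SignalEpoch | Sequence[float], params: EntropyParams
) -> float:
    """Dispatch to the estimator named in ``params.estimator``."""
    return _DISPATCH[params.estimator](epoch, params)


def epoch_feature_matrix(
    signals: np.ndarray | Sequence[Sequence[float]],
    rate: float,
    epoch_len: float,
    params: EntropyParams | None = None,
    labels: Sequence[int] | None = None,
    channel_names: Sequence[str] | None = None,
    on_degenerate: str = "raise",
) -> FeatureMatrix:
    """Entropy feature matrix: entry (p, q) is the entropy of channel q in epoch p.

    ``signals`` is samples x channels (or a per-channel sequence of equal
    lengths). A trailing partial epoch is dropped with a warning. When a
    channel is degenerate within an epoch, ``on_degenerate`` selects the
    policy: ``"raise"`` (default — silent zeros would poison the downstream
    eigenanalysis) or ``"impute"`` with that channel's median over its
    well-defined epochs (logged).
    """
    params = params or EntropyParams()
    if on_degenerate not in {"raise", "impute"}:
        raise ConfigurationError("on_degenerate must be 'raise' or 'impute'")
    arr = np.asarray(signals, dtype=float)
    if arr.ndim != 2:
        # allow a list of per-channel sequences
        lengths = {len(ch) for ch in signals}  # type: ignore[arg-type]
        if len(lengths) != 1:
            raise ConfigurationError("all channels must have equal length")
        arr = np.column_stack([np.asarray(ch, dtype=float) for ch in signals])
    n_samples, n_channels = arr.shape
    step = int(round(epoch_len * rate))
    if step < params.m + 2:
        raise ConfigurationError("epoch too short for the requested embedding")
    n_epochs = n_samples // step
    if n_epochs == 0:
        raise ConfigurationError("signal shorter than one epoch")
    if n_epochs * step != n_samples:
        warnings.warn(
            f"dropping trailing partial epoch ({n_samples - n_epochs * step} samples)",
            stacklevel=2,
        )
        logger.warning("dropping trailing partial epoch")

    out = np.full((n_epochs, n_channels), np.nan)
    for q in range(n_channels):
        for p in range(n_epochs):
            seg = arr[p * step : (p + 1) * step, q]
            try:
                out[p, q] = entropy_of(SignalEpoch(seg, rate), params)
            except DegenerateEpochError:
                if on_degenerate == "raise":
                    raise
                logger.warning("degenerate epoch %d on channel %d; imputing", p, q)
        if np.any(np.isnan(out[:, q])):
            good = out[~np.isnan(out[:, q]), q]
            if good.size == 0:
                raise DegenerateEpochError(f"channel {q} degenerate in every epoch")
            out[np.isnan(out[:, q]), q] = np.median(good)

    return FeatureMatrix(
        values=out,
        labels=None if labels is None else np.asarray(labels)[:n_epochs],
        feature_names=list(channel_names) if channel_names else [],
    )
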