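"""Independent brute-force oracles used to validate the implementations.

These deliberately share no code with the package: template matrices are
materialized explicitly and pair distances come from scipy's cdist (or plain
scalar loops for the kernels).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.distance import cdist


def sample_entropy_oracle(x: np.ndarray, m: int = 2, r_factor: float = 0.25) -> float:
    """O(N^2) pair-counting sample entropy via explicit template matrices."""
    x = np.asarray(x, dtype=float)
    r = r_factor * np.std(x)
    t = x.size - m
    tm = np.array([x[i : i + m] for i in range(t)])
    tm1 = np.array([x[i : i + m + 1] for i in range(t)])
    dm = cdist(tm, tm, "chebyshev")
    dm1 = cdist(tm1, tm1, "chebyshev")
    b = int((dm < r).sum()) - t  # subtract the diagonal self-matches
    a = int((dm1 < r).sum()) - t
    return -math.log(a / b)


def fuzzy_entropy_oracle(
    x: np.ndarray, m: int = 2, r_factor: float = 0.25, n_grad: int = 2
) -> float:
    """Brute-force membership-sum fuzzy entropy on mean-centred templates."""
    x = np.asarray(x, dtype=float)
    r = r_factor * np.std(x)
    t = x.size - m

    def phi(length: int) -> float:
        tm = np.array([x[i : i + length] for i in range(t)])
        tm = tm - tm.mean(axis=1, keepdims=True)
        d = cdist(tm, tm, "chebyshev")
        mu = np.exp(-(d**n_grad) / r)
        return (mu.sum() - t) / (t * (t - 1))  # diagonal memberships are 1

    return math.log(phi(m)) - math.log(phi(m + 1))


def kernel_oracle(x: np.ndarray, y: np.ndarray, family: str, **params) -> np.ndarray:
    """Scalar-loop Gram matrix for every kernel family."""
    out = np.empty((len(x), len(y)))
    for i, xi in enumerate(x):
        for j, yj in enumerate(y):
            dot = sum(float(a) * float(b) for a, b in zip(xi, yj))
            if family == "linear":
                out[i, j] = dot
            elif family == "polynomial":
                out[i, j] = (dot + 1.0) ** params["P"]
            elif family == "rbf":
                sq = sum((float(a) - float(b)) ** 2 for a, b in zip(xi, yj))
                out[i, j] = math.exp(-sq / params["delta"] ** 2)
            elif family == "mlp":
                out[i, j] = math.tanh(params["v"] * dot + params["c"])
            else:
                raise ValueError(family)
    return out


def correlation_eigenvalues_oracle(x: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the feature correlation matrix, built by hand."""
    from scipy.linalg import eigh

    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    y = (x - mean) / sd
    r = y.T @ y / (x.shape[0] - 1)
    vals = eigh(r, eigvals_only=True)
    return vals[::-1]


def cvc_scan_oracle(rates, threshold: float) -> int:
    """Exhaustive scan over k for the smallest cumulative sum >= threshold."""
    total = 0.0
    for k, rate in enumerate(rates, start=1):
        total += rate
        if total >= threshold - 1e-12:
            return k
    return len(rates)
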