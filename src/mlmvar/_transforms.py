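"""Unconstrained-space transforms and prior densities for the sampler.

Scale parameters are sampled on the log scale (half-Cauchy priors plus the
log-transform Jacobian); correlation matrices are sampled through the
canonical-partial-correlation Cholesky transform with an LKJ prior, so
that any real-valued vector maps to a valid positive-definite correlation
matrix.
"""

from __future__ import annotations

import math

import numpy as np

LOG_2PI = math.log(2.0 * math.pi)


def normal_logpdf(x, mu, sd):
    z = (np.asarray(x, dtype=float) - mu) / sd
    return -0.5 * (z * z + LOG_2PI) - np.log(sd)


def half_cauchy_logpdf(x, scale):
    """Density of |Cauchy(0, scale)| for x > 0."""
    x = np.asarray(x, dtype=float)
    return np.log(2.0 / (np.pi * np.asarray(scale, dtype=float))) - np.log1p(
        (x / scale) ** 2
    )


def chol_corr(z: np.ndarray, d: int) -> np.ndarray:
    """Cholesky factor of a correlation matrix from d(d-1)/2 reals.

    Row-major canonical partial correlations y = tanh(z): row i entries
    L[i, j] = y_ij * sqrt(1 - sum_{m<j} L[i, m]^2).
    """
    L = np.zeros((d, d))
    L[0, 0] = 1.0
    y = np.tanh(z)
    k = 0
    for i in range(1, d):
        rem = 1.0
        for j in range(i):
            L[i, j] = y[k] * math.sqrt(rem)
            rem *= 1.0 - y[k] * y[k]
            k += 1
        L[i, i] = math.sqrt(rem)
    return L


def lkj_chol_log_prior(z: np.ndarray, d: int, eta: float = 1.0) -> float:
    """Log density of the LKJ(eta) prior in the unconstrained CPC space.

    Includes the tanh Jacobian: each canonical partial correlation in
    column j (0-based) contributes beta_j * log(1 - y^2) with
    beta_j = eta + (d - 2 - j) / 2, which makes the y independent
    Beta(beta_j, beta_j) variables rescaled to (-1, 1) -- the vine
    construction of the LKJ distribution.
    """
    y = np.tanh(z)
    total = 0.0
    k = 0
    for i in range(1, d):
        for j in range(i):
            beta = eta + (d - 2 - j) / 2.0
            total += beta * math.log1p(-y[k] * y[k])
            k += 1
    return total


def corr_pairs_from_chol(L: np.ndarray) -> np.ndarray:
    """Pairwise correlations in row-major (j < i) order matching names."""
    R = L @ L.T
    d = L.shape[0]
    return np.array([R[i, j] for i in range(1, d) for j in range(i)])
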