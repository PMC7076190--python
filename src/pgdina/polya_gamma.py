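"""Exact Polya-Gamma PG(1, z) random variates.

A PG(b, z) variable is an infinite convolution of gammas,

    W  =  (1 / (2 pi^2)) * sum_k  G_k / ((k - 1/2)^2 + z^2 / (4 pi^2)),
    G_k ~ Gamma(b, 1) iid,

whose Laplace transform for b = 1 is cosh(z/2)^... / cosh(sqrt(z^2/4 + t/2))
(see :func:`pg_laplace`) and whose mean is tanh(z/2) / (2 z).  Only b = 1 is
needed for binary-response augmentation, and that case admits an exact
rejection sampler: PG(1, z) = J*(1, z/2) / 4 where J* is the Jacobi-type
distribution, sampled by Devroye's alternating-series method with a
truncated-inverse-Gaussian / truncated-exponential proposal mixture.  The
acceptance probability is uniformly high (> 0.99), so cost is O(1) per draw.

The inner loop is numba-compiled and consumes a ``numpy.random.Generator``
directly, so draws are reproducible from a single seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["sample_pg", "pg_fill", "pg_mean", "pg_laplace"]

# Devroye's crossover point between the two series regimes of the J* density.
_TRUNC = 0.64


@njit(cache=True)
def _a_coef(n, x):
    # n-th term of the alternating series for the J*(1,0) density at x,
    # using the left (x <= t) or right (x > t) representation.
    if x <= _TRUNC:
        return (
            math.pi * (n + 0.5) * (2.0 / (math.pi * x)) ** 1.5
            * math.exp(-2.0 * (n + 0.5) ** 2 / x)
        )
    return math.pi * (n + 0.5) * math.exp(-((n + 0.5) ** 2) * math.pi**2 * x / 2.0)


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@njit(cache=True)
def _rtigauss(z, t, rng):
    # Inverse-Gaussian(1/z, 1) truncated to (0, t]; z may be 0 (degenerate
    # infinite mean), in which case the chi-squared rejection branch applies
    # with acceptance probability 1.
    x = t + 1.0
    if z < 1.0 / t:
        while True:
            e1 = rng.standard_exponential()
            e2 = rng.standard_exponential()
            while e1 * e1 > 2.0 * e2 / t:
                e1 = rng.standard_exponential()
                e2 = rng.standard_exponential()
            x = t / (1.0 + t * e1) ** 2
            if rng.random() <= math.exp(-0.5 * z * z * x):
                return x
    else:
        mu = 1.0 / z
        while x > t:
            y = rng.standard_normal() ** 2
            muy = mu * y
            x = mu + 0.5 * mu * muy - 0.5 * mu * math.sqrt(4.0 * muy + muy * muy)
            if rng.random() > mu / (mu + x):
                x = mu * mu / x
        return x
    return x


@njit(cache=True)
def _sample_jstar(z, rng):
    # Devroye rejection sampler for J*(1, z), z >= 0.
    t = _TRUNC
    K = math.pi**2 / 8.0 + z * z / 2.0
    p = math.pi / (2.0 * K) * math.exp(-K * t)
    inv_sqrt_t = 1.0 / math.sqrt(t)
    q = 2.0 * (
        math.exp(-z) * _norm_cdf(inv_sqrt_t * (t * z - 1.0))
        + math.exp(z) * _norm_cdf(-inv_sqrt_t * (t * z + 1.0))
    )
    while True:
        if rng.random() < p / (p + q):
            x = t + rng.standard_exponential() / K  # exponential right tail
        else:
            x = _rtigauss(z, t, rng)  # truncated inverse-Gaussian body
        # alternating-series squeeze acceptance
        s = _a_coef(0, x)
        y = rng.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return x
            else:
                s += _a_coef(n, x)
                if y > s:
                    break


@njit(cache=True)
def _pg_fill(z, out, rng):
    for i in range(z.size):
        out[i] = 0.25 * _sample_jstar(abs(z[i]) / 2.0, rng)


def pg_fill(z: np.ndarray, out: np.ndarray, rng: np.random.Generator) -> None:
    """Fill ``out`` (flat, same size as ``z``) with PG(1, z_i) draws in place."""
    _pg_fill(z.reshape(-1), out.reshape(-1), rng)


def sample_pg(z, rng: np.random.Generator, size=None):
    """Draw from PG(1, z).

    ``z`` may be a scalar (optionally replicated ``size`` times) or an array
    (one draw per element).  The distribution depends on z only through |z|.
    """
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("z must be finite")
    scalar = z.ndim == 0 and size is None
    if z.ndim == 0:
        z = np.full(1 if size is None else size, float(z))
    elif size is not None:
        raise ValueError("size is only valid with scalar z")
    out = np.empty(z.size)
    _pg_fill(z.reshape(-1), out, rng)
    return float(out[0]) if scalar else out.reshape(z.shape)


def pg_mean(z):
    """E[PG(1, z)] = tanh(z/2) / (2 z), with the limit 1/4 at z = 0."""
    z = np.asarray(z, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(z == 0.0, 0.25, np.tanh(z / 2.0) / (2.0 * z))
    return float(m) if m.ndim == 0 else m


def pg_laplace(t, z):
    """Laplace transform E[exp(-t W)] = cosh(z/2) / cosh(sqrt(z^2 + 2t)/2) for W ~ PG(1, z)."""
    z = np.asarray(z, dtype=float)
    t = np.asarray(t, dtype=float)
    val = np.cosh(z / 2.0) / np.cosh(np.sqrt(z**2 + 2.0 * t) / 2.0)
    return float(val) if val.ndim == 0 else val
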