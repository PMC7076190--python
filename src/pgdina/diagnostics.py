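"""Convergence diagnostics and posterior summaries.

Implements the Brooks-Gelman corrected potential scale reduction factor
(PSRF) across whole chains,

    R^2 = ( (n-1)/n + (1/n) B/W ) (m+1)/m  -  (n-1)/(m n),

with between-chain variance B = n/(m-1) sum_j (mean_j - grand)^2 and
within-chain variance W = mean of the per-chain sample variances, without
split-chain halving or rank normalization (the convention is multiple
separately-started chains monitored whole; a split option is available).
PSRF < 1.1 is the customary convergence threshold.

Posterior summaries are the EAP (posterior mean), posterior SD, and the
highest-posterior-density interval (shortest window of sorted draws holding
the nominal mass; equal-width ties resolved to the smallest lower bound).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["PsrfTrace", "PosteriorSummary", "psrf", "psrf_trace", "summarize", "hpdi"]


@dataclass(frozen=True)
class PsrfTrace:
    grid: np.ndarray  # increasing iteration checkpoints
    values: np.ndarray  # (len(grid),) or (len(grid), P)


@dataclass(frozen=True)
class PosteriorSummary:
    eap: float
    sd: float
    hpdi: tuple[float, float]
    level: float = 0.95


def psrf(chains, split: bool = False) -> float:
    """Brooks-Gelman PSRF for one parameter from m >= 2 chains of length n >= 4.

    ``chains`` is an (m, n) array (or list of equal-length sequences).  With
    ``split=True`` each chain is halved first, doubling m.  Returns +inf with
    a warning when the within-chain variance is exactly zero.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValueError("chains must be a 2-d (m, n) array")
    if split:
        n2 = x.shape[1] // 2
        x = np.concatenate([x[:, :n2], x[:, n2 : 2 * n2]], axis=0)
    m, n = x.shape
    if m < 2 or n < 4:
        raise ValueError(f"need m >= 2 chains of length n >= 4, got ({m}, {n})")
    means = x.mean(axis=1)
    B = n * means.var(ddof=1)
    W = x.var(axis=1, ddof=1).mean()
    if W == 0.0:
        warnings.warn("zero within-chain variance; PSRF undefined", RuntimeWarning, stacklevel=2)
        return np.inf
    r2 = ((n - 1) / n + B / (n * W)) * (m + 1) / m - (n - 1) / (m * n)
    return float(np.sqrt(r2))


def psrf_trace(chains, grid=None, n_checkpoints: int = 20) -> PsrfTrace:
    """PSRF computed cumulatively on the first g iterations for each grid point g.

    Default grid: ``n_checkpoints`` evenly spaced checkpoints up to the chain
    length (each at least 4 iterations).  ``chains`` may be (m, n) for one
    parameter or (m, n, P) for P parameters monitored jointly.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
        squeeze = True
    elif x.ndim == 3:
        squeeze = False
    else:
        raise ValueError("chains must be (m, n) or (m, n, P)")
    n = x.shape[1]
    if grid is None:
        grid = np.unique(np.linspace(max(4, n // n_checkpoints), n, n_checkpoints).astype(int))
    grid = np.asarray(grid, dtype=int)
    if (np.diff(grid) <= 0).any() or grid[0] < 4 or grid[-1] > n:
        raise ValueError("grid must be increasing, >= 4 and within chain length")
    vals = np.empty((grid.size, x.shape[2]))
    for gi, g in enumerate(grid):
        for p in range(x.shape[2]):
            vals[gi, p] = psrf(x[:, :g, p])
    return PsrfTrace(grid=grid, values=vals[:, 0] if squeeze else vals)


def hpdi(draws, level: float = 0.95) -> tuple[float, float]:
    """Shortest window of sorted draws covering at least ``level`` mass
    (floor(level*n) + 1 points, capped at n)."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    k = min(n, int(np.floor(level * n)) + 1)
    if k < 1:
        raise ValueError("level out of range for the number of draws")
    if k == n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))  # argmin takes the first (smallest lower bound) on ties
    return float(x[i]), float(x[i + k - 1])


def summarize(draws, level: float = 0.95) -> PosteriorSummary:
    """EAP, SD and HPDI of a vector of posterior draws (n >= 10)."""
    x = np.asarray(draws, dtype=float)
    if x.ndim != 1 or x.size < 10:
        raise ValueError("draws must be a 1-d vector with at least 10 entries")
    return PosteriorSummary(
        eap=float(x.mean()),
        sd=float(x.std(ddof=1)),
        hpdi=hpdi(x, level),
        level=level,
    )
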