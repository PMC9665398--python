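"""MCMC convergence diagnostics and posterior interval summaries."""

from __future__ import annotations

import numpy as np

__all__ = ["rhat", "hdi"]


def rhat(draws: np.ndarray) -> float | np.ndarray:
    """Classic Gelman-Rubin potential scale reduction factor.

    Parameters
    ----------
    draws
        Array of shape ``(n_chains, n_iterations)`` or
        ``(n_chains, n_iterations, ...)``; the statistic is computed over
        the first two axes, whole chains (not split halves).

    Returns
    -------
    The PSRF ``sqrt(((n-1)/n * W + B/n) / W)`` where ``W`` is the mean
    within-chain variance and ``B/n`` the variance of the chain means.  A
    parameter with zero total variance (all chains constant and equal)
    returns 1 by convention.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim < 2 or draws.shape[0] < 2 or draws.shape[1] < 2:
        raise ValueError("rhat needs >= 2 chains with >= 2 iterations each")
    n = draws.shape[1]
    chain_means = draws.mean(axis=1)
    w = draws.var(axis=1, ddof=1).mean(axis=0)
    b_over_n = chain_means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * w + b_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(var_plus / w)
    degenerate = (w == 0) & (b_over_n == 0)
    r = np.where(degenerate, 1.0, r)
    return float(r) if r.ndim == 0 else r


def hdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Highest density interval: the shortest contiguous interval of the
    sorted samples containing ``ceil(mass * n)`` of them.
    """
    samples = np.sort(np.asarray(samples, dtype=float).ravel())
    n = samples.size
    if n < 2:
        raise ValueError("hdi needs at least 2 samples")
    if not 0 < mass < 1:
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    k = int(np.ceil(mass * n))
    widths = samples[k - 1 :] - samples[: n - k + 1]
    i = int(np.argmin(widths))
    return float(samples[i]), float(samples[i + k - 1])
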