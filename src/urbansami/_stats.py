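"""Shared statistical helpers: percentile bootstrap and RNG plumbing."""

from __future__ import annotations

import numpy as np


def check_rng(seed_or_rng) -> np.random.Generator:
    """Return a Generator from a seed, a Generator, or None (fresh entropy)."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def bootstrap_mean_ci(
    values: np.ndarray,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    rng=None,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI for the mean of a 1-d sample.

    Resamples the observations with replacement ``n_boot`` times and takes the
    ``alpha/2`` and ``1 - alpha/2`` quantiles of the resampled means.  Returns
    ``(mean, ci_low, ci_high)``.  A constant sample yields a zero-width
    interval.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("bootstrap_mean_ci expects a nonempty 1-d sample")
    rng = check_rng(rng)
    n = values.size
    idx = rng.integers(0, n, size=(n_boot, n))
    means = values[idx].mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(values.mean()), float(lo), float(hi)
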