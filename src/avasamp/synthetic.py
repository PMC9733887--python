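"""Synthetic fixture generators with known ground truth.

These generate the controlled inputs used to validate the estimators:
AR(1) population-activity traces with a known intrinsic timescale (for the
timescale estimator), truncated discrete power-law samples with a known
exponent (for the avalanche fits), and Bernoulli event trains (for
correlation baselines).  Each generator *is* its own oracle: the analysis
code must recover the parameters these were built from.
"""

from __future__ import annotations

import numpy as np

from .avalanches import sample_power_law

__all__ = ["ar1_activity", "power_law_sizes", "bernoulli_events"]


def ar1_activity(
    n_steps: int,
    tau_ms: float,
    dt_ms: float = 2.0,
    innovation_mean: float = 20.0,
    seed: int = 0,
) -> np.ndarray:
    """AR(1) trace ``A(t+1) = b A(t) + Poisson(mu)`` with ``b = exp(-dt/tau)``.

    Mimics the population activity of a driven branching process: slope
    ``b`` encodes the intrinsic timescale, Poisson innovations play the
    role of the external drive ``N h``.  ``tau_ms = 0`` yields white
    Poisson noise.  Stationary mean is ``mu / (1 - b)``.
    """
    rng = np.random.default_rng(seed)
    b = 0.0 if tau_ms == 0 else float(np.exp(-dt_ms / tau_ms))
    a = np.empty(n_steps)
    a[0] = innovation_mean / (1.0 - b)
    noise = rng.poisson(innovation_mean, size=n_steps - 1)
    for t in range(n_steps - 1):
        a[t + 1] = b * a[t] + noise[t]
    return a


def power_law_sizes(
    alpha: float, n: int, s_min: int = 1, s_max: int = 50, seed: int = 0
) -> np.ndarray:
    """``n`` exact draws from the truncated discrete power law."""
    return sample_power_law(alpha, n, s_min, s_max,
                            rng=np.random.default_rng(seed))


def bernoulli_events(
    n_channels: int, n_bins: int, p: float, seed: int = 0
) -> np.ndarray:
    """Independent per-bin event counts, shape (n_channels, n_bins)."""
    rng = np.random.default_rng(seed)
    return (rng.random((n_channels, n_bins)) < p).astype(np.int64)
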