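"""Avalanche statistics: binning, decomposition, power-law fits, m_av.

Events from all channels are binned at a bin size ``dt_bin`` and summed.
An avalanche is a maximal run of consecutive non-empty bins, bounded by
empty bins; its size ``S`` is the total event count in the run and its
duration ``D`` the number of bins.  Size distributions are fitted with a
discrete maximum-likelihood power law ``p(S) ~ S**-alpha`` on a bounded
integer support (default S in [1, 50]); the systematic dependence of the
fitted exponent on bin size is summarised by ``alpha ~ dt_bin**-beta``.
The avalanche-based branching-parameter estimate ``m_av`` is the average
ratio of event counts in consecutive bins within avalanches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .events import EventSeries

__all__ = [
    "BinnedActivity",
    "AvalancheSet",
    "PowerLawFit",
    "BinScalingFit",
    "bin_events",
    "cut_avalanches",
    "size_distribution",
    "duration_distribution",
    "fit_power_law",
    "fit_bin_scaling",
    "branching_from_avalanches",
    "distribution_ks_distance",
]

DEFAULT_FIT_RANGE = (1, 50)


@dataclass
class BinnedActivity:
    """Per-bin event counts summed over all channels."""

    counts: np.ndarray
    dt_bin_ms: float

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total_events(self) -> int:
        return int(self.counts.sum())


@dataclass
class AvalancheSet:
    """Sizes and durations of all complete avalanches in a recording.

    Avalanches still open at the record edges are discarded (their S and D
    are undefined); ``discarded_events`` counts the events they contained,
    so ``sizes.sum() + discarded_events`` equals the total event count.
    """

    sizes: np.ndarray
    durations: np.ndarray
    dt_bin_ms: float
    discarded_events: int = 0

    @property
    def n_avalanches(self) -> int:
        return len(self.sizes)


def bin_events(events: EventSeries, dt_bin_ms: float) -> BinnedActivity:
    """Stage III: bin all channels' events at ``dt_bin_ms`` and sum.

    Bin ``b`` counts events with ``b*dt <= t < (b+1)*dt``; bins are anchored
    at t = 0 and cover the full recording length.
    """
    if dt_bin_ms <= 0:
        raise ValueError("dt_bin_ms must be > 0")
    n_bins = max(int(np.ceil(events.duration_ms / dt_bin_ms)), 1)
    pooled = events.pooled()
    idx = np.floor(pooled / dt_bin_ms).astype(np.int64)
    if len(idx) and (idx.min() < 0 or idx.max() >= n_bins):
        raise ValueError("event timestamps outside [0, duration)")
    return BinnedActivity(
        counts=np.bincount(idx, minlength=n_bins), dt_bin_ms=float(dt_bin_ms)
    )


def cut_avalanches(
    binned: BinnedActivity, discard_edges: bool = True
) -> AvalancheSet:
    """Stage IV: maximal runs of non-empty bins bounded by empty bins.

    A new avalanche starts at a non-empty bin preceded by an empty bin and
    ends at the next empty bin.  A run still open at a record edge is a
    truncated cascade whose true S and D are unknown; by default it is
    dropped and its events counted in ``discarded_events``.  With
    ``discard_edges=False`` the record edges act as avalanche boundaries
    and such runs are kept.
    """
    c = np.asarray(binned.counts, dtype=np.int64)
    occupied = c > 0
    if not occupied.any():
        return AvalancheSet(
            sizes=np.empty(0, dtype=np.int64),
            durations=np.empty(0, dtype=np.int64),
            dt_bin_ms=binned.dt_bin_ms,
        )
    edges = np.diff(occupied.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    stops = np.nonzero(edges == -1)[0] + 1
    if occupied[0]:
        starts = np.concatenate([[0], starts])
    if occupied[-1]:
        stops = np.concatenate([stops, [len(c)]])
    discarded = 0
    if discard_edges:
        if occupied[0]:
            discarded += int(c[starts[0] : stops[0]].sum())
            starts, stops = starts[1:], stops[1:]
        if len(starts) and occupied[-1]:
            discarded += int(c[starts[-1] : stops[-1]].sum())
            starts, stops = starts[:-1], stops[:-1]
    csum = np.concatenate([[0], np.cumsum(c)])
    sizes = csum[stops] - csum[starts]
    return AvalancheSet(
        sizes=sizes.astype(np.int64),
        durations=(stops - starts).astype(np.int64),
        dt_bin_ms=binned.dt_bin_ms,
        discarded_events=discarded,
    )


def size_distribution(avs: AvalancheSet) -> tuple[np.ndarray, np.ndarray]:
    """Normalised histogram p(S): returns (unique sizes, probabilities)."""
    if avs.n_avalanches == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    s, counts = np.unique(avs.sizes, return_counts=True)
    return s, counts / counts.sum()


def duration_distribution(avs: AvalancheSet) -> tuple[np.ndarray, np.ndarray]:
    """Normalised histogram p(D) over avalanche durations (in bins)."""
    if avs.n_avalanches == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    d, counts = np.unique(avs.durations, return_counts=True)
    return d, counts / counts.sum()


@dataclass
class PowerLawFit:
    """Discrete MLE fit of ``p(S) ~ S**-alpha`` on ``s_min <= S <= s_max``."""

    alpha: float
    s_min: int
    s_max: int
    n: int  # samples inside the fit range
    ks_distance: float
    degenerate: bool = False
    method: str = "discrete-mle-truncated"

    def pmf(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        support = np.arange(self.s_min, self.s_max + 1, dtype=float)
        z = (support ** -self.alpha).sum()
        out = np.where(
            (s >= self.s_min) & (s <= self.s_max), s ** -self.alpha / z, 0.0
        )
        return out


class InsufficientData(ValueError):
    """Raised when too few avalanches fall inside the fit range."""

    def __init__(self, n: int, needed: int):
        self.n = n
        self.needed = needed
        super().__init__(
            f"only {n} samples in fit range (need >= {needed})"
        )


def _truncated_alpha_mle(
    s: np.ndarray, s_min: int, s_max: int
) -> tuple[float, bool]:
    """Maximise the truncated zeta likelihood; flags boundary solutions."""
    support = np.arange(s_min, s_max + 1, dtype=float)
    log_s_mean = np.log(s).mean()

    def nll(alpha: float) -> float:
        z = np.exp(-alpha * np.log(support)).sum()
        return alpha * log_s_mean + np.log(z)

    res = optimize.minimize_scalar(nll, bounds=(1e-3, 20.0), method="bounded")
    alpha = float(res.x)
    degenerate = alpha <= 2e-3 or alpha >= 19.9
    return alpha, degenerate


def fit_power_law(
    sizes: np.ndarray,
    s_min: int = DEFAULT_FIT_RANGE[0],
    s_max: int = DEFAULT_FIT_RANGE[1],
    min_samples: int = 100,
) -> PowerLawFit:
    """Discrete maximum-likelihood power-law fit on a bounded support.

    Only samples with ``s_min <= S <= s_max`` enter the likelihood, whose
    normaliser is the truncated zeta sum over the integer support.  The KS
    distance between the empirical and fitted CDFs (within the range) is
    returned as a goodness diagnostic.  A fit driven to the search boundary
    (e.g. all sizes equal) is flagged ``degenerate``.
    """
    sizes = np.asarray(sizes)
    if s_min < 1 or s_max <= s_min:
        raise ValueError("need 1 <= s_min < s_max")
    s = sizes[(sizes >= s_min) & (sizes <= s_max)].astype(float)
    if len(s) < min_samples:
        raise InsufficientData(len(s), min_samples)
    alpha, degenerate = _truncated_alpha_mle(s, s_min, s_max)
    if np.ptp(s) == 0:
        degenerate = True

    support = np.arange(s_min, s_max + 1)
    pmf = support ** (-alpha) / (support ** (-alpha)).sum()
    model_cdf = np.cumsum(pmf)
    emp_cdf = np.searchsorted(np.sort(s), support, side="right") / len(s)
    ks = float(np.abs(emp_cdf - model_cdf).max())
    return PowerLawFit(
        alpha=alpha,
        s_min=int(s_min),
        s_max=int(s_max),
        n=len(s),
        ks_distance=ks,
        degenerate=degenerate,
    )


def sample_power_law(
    alpha: float,
    size: int,
    s_min: int = DEFAULT_FIT_RANGE[0],
    s_max: int = DEFAULT_FIT_RANGE[1],
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Exact inverse-CDF draws from the truncated discrete power law."""
    rng = np.random.default_rng() if rng is None else rng
    support = np.arange(s_min, s_max + 1)
    pmf = support ** (-float(alpha))
    pmf = pmf / pmf.sum()
    return rng.choice(support, size=size, p=pmf)


@dataclass
class BinScalingFit:
    """Least-squares fit of ``alpha ~ dt_bin**-beta`` on log-log axes."""

    beta: float
    intercept: float
    pairs: list[tuple[float, float]]  # (dt_bin_ms, alpha)


def fit_bin_scaling(pairs) -> BinScalingFit:
    """``beta = -slope`` of ln(alpha) versus ln(dt_bin) over >= 3 bin sizes."""
    pairs = [(float(dt), float(a)) for dt, a in pairs]
    if len({dt for dt, _ in pairs}) < 3:
        raise ValueError("need >= 3 distinct bin sizes")
    x = np.log([dt for dt, _ in pairs])
    y = np.log([a for _, a in pairs])
    slope, intercept = np.polyfit(x, y, 1)
    return BinScalingFit(beta=float(-slope), intercept=float(intercept),
                         pairs=pairs)


def branching_from_avalanches(
    binned: BinnedActivity,
    avs: AvalancheSet | None = None,
    method: str = "weighted",
) -> float:
    """Avalanche-based branching-parameter estimate ``m_av``.

    The average ratio of event counts between subsequent time bins during
    non-zero activity, i.e. over consecutive-bin pairs inside avalanches.
    "Average ratio" admits several conventions:

    * ``"weighted"`` (default): ratio of totals,
      ``sum(n_{b+1}) / sum(n_b)`` over in-avalanche pairs — each pair's
      ratio weighted by its parent count.  This is the consistent estimate
      of the mean number of descendants per event and the convention under
      which an avalanche sweet spot reads m_av ~ 1.
    * ``"pooled"``: unweighted arithmetic mean of the per-pair ratios
      ``n_{b+1}/n_b`` (upward-biased for small counts by Jensen's
      inequality: pairs (1,2) and (2,1) average to 1.25).
    * ``"per_avalanche"``: per-pair ratios averaged within each avalanche
      of duration >= 2, then across avalanches.

    ``avs``, when given, is only used to cross-check the bin size.
    """
    if avs is not None and avs.dt_bin_ms != binned.dt_bin_ms:
        raise ValueError("binned and avs have different bin sizes")
    c = np.asarray(binned.counts, dtype=float)
    occupied = c > 0
    inside = occupied[:-1] & occupied[1:]
    if not inside.any():
        raise ValueError("no avalanche of duration >= 2; m_av undefined")
    nxt, prev = c[1:][inside], c[:-1][inside]
    if method == "weighted":
        return float(nxt.sum() / prev.sum())
    ratios = nxt / prev
    if method == "pooled":
        return float(ratios.mean())
    if method == "per_avalanche":
        idx = np.nonzero(inside)[0]
        breaks = np.nonzero(np.diff(idx) > 1)[0] + 1
        groups = np.split(ratios, breaks)
        return float(np.mean([g.mean() for g in groups]))
    raise ValueError(f"unknown method {method!r}")


def distribution_ks_distance(sizes_a: np.ndarray, sizes_b: np.ndarray) -> float:
    """Two-sample KS distance between avalanche-size distributions."""
    a = np.sort(np.asarray(sizes_a, dtype=float))
    b = np.sort(np.asarray(sizes_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    grid = np.unique(np.concatenate([a, b]))
    cdf_a = np.searchsorted(a, grid, side="right") / len(a)
    cdf_b = np.searchsorted(b, grid, side="right") / len(b)
    return float(np.abs(cdf_a - cdf_b).max())
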