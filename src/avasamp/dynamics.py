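"""Driven branching-process dynamics on a spatial network.

Binary neurons update in discrete steps of ``dt`` (default 2 ms).  An active
neuron attempts to activate each of its targets ``j`` with probability
``p_ij = m * w_ij`` — the branching parameter ``m`` is the expected number
of recurrent offspring per spike — and every neuron additionally spikes
spontaneously with probability ``h`` per step.  The pair (m, h) fixes the
stationary per-neuron rate ``r = h / (dt * (1 - m))`` and the intrinsic
timescale ``tau = -dt / ln(m)`` of the population activity.

Simultaneous activations of a shared target (coalescence) would silently
lower the effective branching parameter in a locally-connected network;
they are compensated by redirecting the blocked activation to the next
quiescent neuron in the source's distance-sorted target list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._kernels import run_branching
from .topology import NetworkTopology

__all__ = [
    "DynamicState",
    "SimulationResult",
    "NAMED_STATES",
    "named_state",
    "analytic_timescale",
    "drive_for_rate",
    "step",
    "simulate",
    "estimate_timescale",
]

#: Default simulation step in ms (comparable to synaptic transmission).
DEFAULT_DT_MS = 2.0
#: Default stationary per-neuron rate in Hz (fixed across states so that
#: comparisons between dynamic states are free of rate effects).
DEFAULT_RATE_HZ = 1.0


def analytic_timescale(m: float, dt: float) -> float:
    """Intrinsic timescale ``tau = -dt / ln(m)`` of a branching process.

    ``tau`` is the exponential autocorrelation time of the population
    activity.  ``m = 0`` (memoryless Poisson dynamics) gives ``tau = 0``;
    ``m >= 1`` is rejected since ``tau`` diverges.  Units follow ``dt``.
    """
    if not 0.0 <= m < 1.0:
        raise ValueError(f"m must be in [0, 1), got {m}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if m == 0.0:
        return 0.0
    return -dt / np.log(m)


def drive_for_rate(r_hz: float, m: float, dt_ms: float) -> float:
    """Per-neuron spontaneous spike probability ``h`` that yields rate ``r``.

    From the stationarity relation ``r = h / (dt * (1 - m))``:
    ``h = r * dt * (1 - m)`` with ``dt`` converted to seconds.
    """
    if not 0.0 <= m < 1.0:
        raise ValueError(f"m must be in [0, 1), got {m}")
    if r_hz < 0 or dt_ms <= 0:
        raise ValueError("need r_hz >= 0 and dt_ms > 0")
    h = r_hz * (dt_ms / 1000.0) * (1.0 - m)
    if h > 1.0:
        raise ValueError(f"resulting h={h} exceeds 1; lower the rate or dt")
    return h


@dataclass(frozen=True)
class DynamicState:
    """A point in (m, h) space, i.e. a distance to criticality at fixed rate.

    Attributes
    ----------
    m : branching parameter in [0, 1).
    h : spontaneous spike probability per neuron per step.
    dt_ms : simulation step in ms.
    name : label ("poisson", "subcritical", "reverberating", "critical",
        or anything for custom states).
    """

    m: float
    h: float
    dt_ms: float = DEFAULT_DT_MS
    name: str = "custom"

    def __post_init__(self):
        if not 0.0 <= self.m < 1.0:
            raise ValueError(f"m must be in [0, 1), got {self.m}")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError(f"h must be in [0, 1], got {self.h}")

    @property
    def tau_ms(self) -> float:
        """Analytic intrinsic timescale in ms."""
        return analytic_timescale(self.m, self.dt_ms)

    @property
    def rate_hz(self) -> float:
        """Stationary per-neuron rate implied by (m, h, dt)."""
        return self.h / ((self.dt_ms / 1000.0) * (1.0 - self.m))

    @classmethod
    def from_rate(
        cls, name: str, m: float, r_hz: float = DEFAULT_RATE_HZ,
        dt_ms: float = DEFAULT_DT_MS,
    ) -> "DynamicState":
        return cls(m=m, h=drive_for_rate(r_hz, m, dt_ms), dt_ms=dt_ms, name=name)


#: The four canonical dynamic states, all at 1 Hz per neuron and dt = 2 ms:
#: memoryless Poisson (m=0), subcritical (m=0.9, tau ~ 19 ms), reverberating
#: (m=0.98, tau ~ 99 ms; typical of awake cortex) and near-critical
#: (m=0.999, tau ~ 2 s).
NAMED_STATES: dict[str, DynamicState] = {
    name: DynamicState.from_rate(name, m)
    for name, m in [
        ("poisson", 0.0),
        ("subcritical", 0.9),
        ("reverberating", 0.98),
        ("critical", 0.999),
    ]
}


def named_state(name: str, dt_ms: float = DEFAULT_DT_MS) -> DynamicState:
    """Return one of the four canonical states (optionally at another dt)."""
    try:
        s = NAMED_STATES[name]
    except KeyError:
        raise KeyError(
            f"unknown state {name!r}; choose from {sorted(NAMED_STATES)}"
        ) from None
    if dt_ms == s.dt_ms:
        return s
    return DynamicState.from_rate(name, s.m, DEFAULT_RATE_HZ, dt_ms)


def step(
    active: np.ndarray,
    topology: NetworkTopology,
    state: DynamicState,
    rng: np.random.Generator,
    compensate: bool = True,
) -> np.ndarray:
    """One update of the branching dynamics (reference implementation).

    Active neurons are processed in index order and their targets in
    distance order; each connection succeeds independently with
    ``p_ij = m * w_ij``.  A success on a target already marked active for
    the next step is redirected (if ``compensate``) to the next quiescent
    neuron in the source's distance-sorted list, wrapping once; if every
    target is marked, the activation is dropped.  Spontaneous spikes with
    probability ``h`` per neuron are added afterwards.

    This is the plain, per-connection formulation kept as an executable
    reference; :func:`simulate` runs an exact accelerated equivalent.
    Returns the sorted array of next-step active neuron indices.
    """
    n = topology.n_neurons
    next_flag = np.zeros(n, dtype=bool)
    m = state.m
    for i in np.sort(np.asarray(active, dtype=np.int64)):
        lo, hi = topology.indptr[i], topology.indptr[i + 1]
        row_t = topology.targets[lo:hi]
        row_w = topology.weights[lo:hi]
        hits = np.nonzero(rng.random(hi - lo) < m * row_w)[0]
        for k in hits:
            j = row_t[k]
            if not next_flag[j]:
                next_flag[j] = True
            elif compensate:
                walk = np.concatenate([row_t[k + 1 :], row_t[:k]])
                quiet = walk[~next_flag[walk]]
                if len(quiet):
                    next_flag[quiet[0]] = True
    if state.h > 0:
        next_flag |= rng.random(n) < state.h
    return np.nonzero(next_flag)[0]


@dataclass
class SimulationResult:
    """Sparse spike raster plus bookkeeping of one simulation run.

    ``spike_steps``/``spike_neurons`` list the (step, neuron) activations
    after burn-in; step 0 is the first post-burn-in step.
    """

    spike_steps: np.ndarray
    spike_neurons: np.ndarray
    n_steps: int
    n_neurons: int
    dt_ms: float
    state: DynamicState
    seed: int
    burn_in_steps: int = 0
    n_saturated: int = 0
    truncated: bool = False

    @property
    def activity(self) -> np.ndarray:
        """Population activity A(t): number of active neurons per step."""
        return np.bincount(self.spike_steps, minlength=self.n_steps)

    @property
    def spike_times_ms(self) -> np.ndarray:
        return self.spike_steps * self.dt_ms

    @property
    def mean_rate_hz(self) -> float:
        """Mean per-neuron rate over the recorded window."""
        duration_s = self.n_steps * self.dt_ms / 1000.0
        return len(self.spike_steps) / (self.n_neurons * duration_s)


def default_burn_in(state: DynamicState) -> int:
    """Equilibration window: max(1000 steps, 10 tau)."""
    return max(1000, int(np.ceil(10.0 * state.tau_ms / state.dt_ms)))


def simulate(
    topology: NetworkTopology,
    state: DynamicState,
    n_steps: int,
    seed: int = 0,
    burn_in: int | None = None,
    compensate: bool = True,
    max_spikes: int | None = None,
) -> SimulationResult:
    """Run the branching dynamics for ``n_steps`` recorded steps.

    Starts all-quiescent, discards ``burn_in`` equilibration steps (default
    ``max(1000, 10 tau/dt)``), and returns the sparse raster.  Sustained
    saturation (all neurons active) is flagged on the result, not fatal.

    ``max_spikes`` caps the spike buffer; the default is three times the
    expected stationary count.  If the cap is hit the run stops early and
    the result is marked ``truncated``.
    """
    if burn_in is None:
        burn_in = default_burn_in(state)
    total = int(n_steps) + int(burn_in)
    expected = state.rate_hz * topology.n_neurons * total * state.dt_ms / 1000.0
    if max_spikes is None:
        max_spikes = int(3 * expected) + 200_000
    sp_t, sp_i, steps_done, n_sat, overflowed = run_branching(
        topology.indptr,
        topology.targets,
        topology.weights,
        float(state.m),
        float(state.h),
        total,
        topology.n_neurons,
        int(seed) & 0x7FFFFFFF,
        int(max_spikes),
        compensate,
    )
    if overflowed:
        warnings.warn(
            f"spike buffer ({max_spikes}) filled after {steps_done} steps; "
            "result truncated (likely runaway activity)"
        )
    if n_sat > 0:
        warnings.warn(f"activity saturated (A = N) during {n_sat} steps")
    keep = sp_t >= burn_in
    return SimulationResult(
        spike_steps=sp_t[keep] - burn_in,
        spike_neurons=sp_i[keep],
        n_steps=max(steps_done - burn_in, 0),
        n_neurons=topology.n_neurons,
        dt_ms=state.dt_ms,
        state=state,
        seed=int(seed),
        burn_in_steps=int(burn_in),
        n_saturated=int(n_sat),
        truncated=bool(overflowed),
    )


def estimate_timescale(
    activity: np.ndarray, dt_ms: float
) -> float:
    """Intrinsic timescale from an AR(1) fit of the population activity.

    Fits ``A(t+1) = b * A(t) + c`` by ordinary least squares and maps the
    slope to ``tau_hat = -dt / ln(b)``.  A non-positive slope (no memory)
    yields 0 with a warning; a slope >= 1 (non-stationary fit) yields inf
    with a warning.  Raises on constant input.
    """
    a = np.asarray(activity, dtype=float)
    if a.ndim != 1 or len(a) < 3:
        raise ValueError("activity must be a 1D series of length >= 3")
    x, y = a[:-1], a[1:]
    vx = x.var()
    if vx == 0:
        raise ValueError("activity series is constant; AR(1) fit undefined")
    b = ((x - x.mean()) * (y - y.mean())).mean() / vx
    if b <= 0.0:
        warnings.warn(f"AR(1) slope {b:.3g} <= 0; returning tau = 0")
        return 0.0
    if b >= 1.0:
        warnings.warn(f"AR(1) slope {b:.3g} >= 1; returning tau = inf")
        return float("inf")
    return -dt_ms / np.log(b)
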