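"""From continuous channel signals to discrete event timestamps.

The coarse-sampled signal is band-pass filtered (0.1–200 Hz by default,
which demeans and smoothes it), each channel is thresholded at three
standard deviations of its own filtered trace, and one event is placed per
positive excursion — at the single largest maximum between two crossings of
the mean (zero, after demeaning).  After this stage coarse- and sub-sampled
data share the same representation (per-channel timestamps), so everything
downstream is sampling-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["ThresholdSpec", "EventSeries", "bandpass", "extract_events"]


@dataclass(frozen=True)
class ThresholdSpec:
    """Event-detection parameters.

    ``multiplier`` is the threshold in units of each channel's standard
    deviation; ``low_hz``/``high_hz`` are the band edges; ``order`` the
    Butterworth order (applied forward-backward, so zero-phase).
    """

    multiplier: float = 3.0
    low_hz: float = 0.1
    high_hz: float = 200.0
    order: int = 4

    def __post_init__(self):
        if self.multiplier <= 0:
            raise ValueError("multiplier must be > 0")
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")


@dataclass
class EventSeries:
    """Per-channel ordered event timestamps in ms.

    The common currency of the pipeline: produced either by thresholding
    coarse signals (:func:`extract_events`) or directly from a
    :class:`~avasamp.sampling.SpikeRecord`.
    """

    timestamps_ms: list[np.ndarray]
    duration_ms: float
    dt_ms: float
    threshold_multiplier: float | None = None
    band_hz: tuple[float, float] | None = None

    @property
    def n_channels(self) -> int:
        return len(self.timestamps_ms)

    @property
    def n_events(self) -> int:
        return int(sum(len(t) for t in self.timestamps_ms))

    def pooled(self) -> np.ndarray:
        """All events from all channels, sorted, in ms."""
        if not self.timestamps_ms:
            return np.empty(0)
        return np.sort(np.concatenate(self.timestamps_ms))

    @classmethod
    def from_spike_record(cls, rec) -> "EventSeries":
        """Adopt a sub-sampled SpikeRecord (spikes are events by nature)."""
        return cls(
            timestamps_ms=[np.asarray(t, dtype=float) for t in rec.timestamps_ms],
            duration_ms=rec.duration_ms,
            dt_ms=rec.dt_ms,
        )


def bandpass(
    x: np.ndarray, low_hz: float, high_hz: float, fs_hz: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Implemented as second-order sections and applied with ``sosfiltfilt``,
    so event times are not phase-shifted and the design stays stable even
    with the upper edge close to Nyquist.
    """
    if not 0 < low_hz < high_hz < fs_hz / 2:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must lie inside (0, fs/2="
            f"{fs_hz / 2}) Hz"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs_hz,
                     output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def _positive_runs(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start (inclusive) and stop (exclusive) indices of runs with x > 0."""
    pos = x > 0
    edges = np.diff(pos.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    stops = np.nonzero(edges == -1)[0] + 1
    if pos[0]:
        starts = np.concatenate([[0], starts])
    if pos[-1]:
        stops = np.concatenate([stops, [len(x)]])
    return starts, stops


def extract_events(
    filtered: np.ndarray,
    spec: ThresholdSpec = ThresholdSpec(),
    dt_ms: float = 2.0,
) -> EventSeries:
    """One event per supra-threshold positive excursion of each channel.

    ``filtered`` is (n_channels, T), already band-passed and hence
    (virtually) zero-mean.  Per channel, the threshold is
    ``multiplier * std`` of the full trace.  A positive excursion is a
    maximal run of strictly positive samples; it yields exactly one event —
    at its single largest maximum — iff that maximum exceeds the threshold.
    Excursions truncated by the recording edge are kept only when their
    maximum is interior (an edge maximum is ambiguous).
    """
    filtered = np.atleast_2d(np.asarray(filtered, dtype=float))
    out: list[np.ndarray] = []
    t_total = filtered.shape[1]
    for ch in filtered:
        theta = spec.multiplier * ch.std()
        if not np.any(ch > 0) or theta == 0:
            out.append(np.empty(0))
            continue
        starts, stops = _positive_runs(ch)
        run_max = np.maximum.reduceat(ch, starts)
        hit = run_max > theta
        times = []
        for s, e in zip(starts[hit], stops[hit]):
            imax = s + int(np.argmax(ch[s:e]))
            if (s == 0 and imax == 0) or (e == t_total and imax == t_total - 1):
                continue  # edge-truncated excursion with ambiguous maximum
            times.append(imax)
        out.append(np.asarray(times, dtype=float) * dt_ms)
    return EventSeries(
        timestamps_ms=out,
        duration_ms=t_total * dt_ms,
        dt_ms=dt_ms,
        threshold_multiplier=spec.multiplier,
        band_hz=(spec.low_hz, spec.high_hz),
    )
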