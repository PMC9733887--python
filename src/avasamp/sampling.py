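"""Virtual electrode arrays: coarse-sampling and spike sub-sampling.

An 8 x 8 grid of point-like electrodes is centred in the periodic square.
Each electrode yields two read-outs of the same simulation:

* coarse-sampling (LFP-like): ``V_k(t) = sum_i s_i(t) / d_ik**gamma`` —
  every neuron contributes, weighted by its inverse distance to the
  electrode.  ``gamma = 1`` is a wide field of view, ``gamma = 2`` a narrow
  one.  Divergence is prevented by the dead zone around each electrode.
* sub-sampling (spikes): only the single neuron closest to the electrode is
  observed; its spike timestamps are recorded, all other neurons ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse
from scipy import stats

from .topology import DEFAULT_DEAD_ZONE
from .dynamics import SimulationResult

__all__ = [
    "ElectrodeArray",
    "CoarseRecord",
    "SpikeRecord",
    "place_electrodes",
    "electrode_neuron_distances",
    "coarse_signal",
    "subsample_spikes",
    "channel_correlation",
    "adjacent_pairs",
]

DEFAULT_GAMMA = 1.0


@dataclass
class ElectrodeArray:
    """Regular grid of virtual electrodes centred in the system.

    ``positions`` has shape (n_rows * n_cols, 2) in um, row-major.
    """

    n_rows: int
    n_cols: int
    pitch: float  # inter-electrode distance d_E, um
    positions: np.ndarray
    dead_zone_radius: float = DEFAULT_DEAD_ZONE
    gamma: float = DEFAULT_GAMMA

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def span(self) -> float:
        """Linear extent of the grid, (n_cols - 1) * d_E, um."""
        return (max(self.n_rows, self.n_cols) - 1) * self.pitch


def place_electrodes(
    grid: tuple[int, int],
    d_e: float,
    system_size: float,
    dead_zone_radius: float = DEFAULT_DEAD_ZONE,
    gamma: float = DEFAULT_GAMMA,
) -> ElectrodeArray:
    """Centre a ``grid = (rows, cols)`` array of pitch ``d_e`` (um) in the box.

    Rejects arrays whose span does not fit inside the system.
    """
    rows, cols = grid
    if rows < 1 or cols < 1 or d_e <= 0:
        raise ValueError("grid dims must be >= 1 and d_e > 0")
    span = (max(rows, cols) - 1) * d_e
    if not span < system_size:
        raise ValueError(
            f"electrode array span {span} um does not fit in system of "
            f"size {system_size} um"
        )
    x0 = (system_size - (cols - 1) * d_e) / 2.0
    y0 = (system_size - (rows - 1) * d_e) / 2.0
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    pos = np.column_stack([x0 + jj.ravel() * d_e, y0 + ii.ravel() * d_e])
    return ElectrodeArray(
        n_rows=rows,
        n_cols=cols,
        pitch=float(d_e),
        positions=pos,
        dead_zone_radius=float(dead_zone_radius),
        gamma=float(gamma),
    )


def electrode_neuron_distances(
    neuron_positions: np.ndarray, array: ElectrodeArray, box_size: float
) -> np.ndarray:
    """(N, n_electrodes) minimum-image distances in um."""
    d = np.abs(neuron_positions[:, None, :] - array.positions[None, :, :])
    d = np.minimum(d, box_size - d)
    return np.sqrt((d ** 2).sum(axis=-1))


@dataclass
class CoarseRecord:
    """Continuous multichannel signal: ``signal`` is (n_channels, T)."""

    signal: np.ndarray
    dt_ms: float
    gamma: float
    pitch: float

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_steps(self) -> int:
        return self.signal.shape[1]


@dataclass
class SpikeRecord:
    """Per-channel spike timestamps (ms) of each electrode's closest neuron."""

    timestamps_ms: list[np.ndarray]
    neuron_ids: np.ndarray  # electrode -> observed neuron
    dt_ms: float
    duration_ms: float

    @property
    def n_channels(self) -> int:
        return len(self.timestamps_ms)


def coarse_signal(
    result: SimulationResult,
    neuron_positions: np.ndarray,
    array: ElectrodeArray,
    box_size: float,
    gamma: float | None = None,
) -> CoarseRecord:
    """LFP-like record: ``V_k(t) = sum_i s_i(t) / d_ik**gamma``.

    All neurons contribute at every step they spike; contributions are
    strictly positive and instantaneous.  The per-spike contribution matrix
    is applied to the sparse raster with a sparse matmul.
    """
    g = array.gamma if gamma is None else float(gamma)
    if g <= 0:
        raise ValueError(f"gamma must be > 0, got {g}")
    dist = electrode_neuron_distances(neuron_positions, array, box_size)
    contrib = dist ** (-g)  # (N, n_e); bounded by the dead zone
    raster = scipy.sparse.coo_matrix(
        (
            np.ones(len(result.spike_steps), dtype=np.float64),
            (result.spike_steps, result.spike_neurons),
        ),
        shape=(result.n_steps, result.n_neurons),
    ).tocsr()
    v = raster @ contrib  # (T, n_e)
    return CoarseRecord(
        signal=np.ascontiguousarray(v.T),
        dt_ms=result.dt_ms,
        gamma=g,
        pitch=array.pitch,
    )


def subsample_spikes(
    result: SimulationResult,
    neuron_positions: np.ndarray,
    array: ElectrodeArray,
    box_size: float,
) -> SpikeRecord:
    """Spike record: each electrode observes only its single closest neuron.

    Nearest-neuron assignment is deterministic; an exact distance tie is
    resolved in favour of the lowest neuron index.  The same neuron may be
    observed by several electrodes if it is genuinely nearest to each.
    """
    dist = electrode_neuron_distances(neuron_positions, array, box_size)
    nearest = np.argmin(dist, axis=0)  # first minimum -> lowest index
    per_channel = []
    for k in range(array.n_electrodes):
        steps = result.spike_steps[result.spike_neurons == nearest[k]]
        per_channel.append(np.sort(steps) * result.dt_ms)
    return SpikeRecord(
        timestamps_ms=per_channel,
        neuron_ids=nearest.astype(np.int64),
        dt_ms=result.dt_ms,
        duration_ms=result.n_steps * result.dt_ms,
    )


def channel_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two equally long channel series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1D and equally long")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input")
    return float(stats.pearsonr(a, b)[0])


def adjacent_pairs(array: ElectrodeArray) -> list[tuple[int, int]]:
    """Index pairs of horizontally/vertically adjacent electrodes."""
    pairs = []
    for r in range(array.n_rows):
        for c in range(array.n_cols):
            k = r * array.n_cols + c
            if c + 1 < array.n_cols:
                pairs.append((k, k + 1))
            if r + 1 < array.n_rows:
                pairs.append((k, k + array.n_cols))
    return pairs
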