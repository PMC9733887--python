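"""Plain-text and HDF5 persistence for the pipeline's data types.

The interchange format for discrete events is a two-column TSV
``(channel_id, time_ms)`` — identical for sub-sampled spikes and for
events extracted from coarse signals, so spike-sorted experimental data can
be dropped into the avalanche analysis unchanged.  Continuous multichannel
signals travel as HDF5 (channel x time, with a ``dt_ms`` attribute) or CSV
for small fixtures; topologies as HDF5 with ragged CSR arrays.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .events import EventSeries
from .sampling import CoarseRecord, SpikeRecord
from .topology import NetworkTopology

__all__ = [
    "write_events_tsv",
    "read_events_tsv",
    "write_coarse_h5",
    "read_coarse_h5",
    "write_coarse_csv",
    "read_coarse_csv",
    "write_topology_h5",
    "read_topology_h5",
    "write_topology_tsv",
    "write_raster_tsv",
]


def _events_like(obj) -> EventSeries:
    if isinstance(obj, SpikeRecord):
        return EventSeries.from_spike_record(obj)
    return obj


def write_events_tsv(path, events: EventSeries | SpikeRecord) -> None:
    """(channel_id, time_ms) rows, tab-separated, sorted by channel."""
    ev = _events_like(events)
    chans = np.concatenate(
        [np.full(len(t), k) for k, t in enumerate(ev.timestamps_ms)]
        or [np.empty(0, dtype=int)]
    )
    times = np.concatenate(ev.timestamps_ms or [np.empty(0)])
    pd.DataFrame({"channel_id": chans.astype(int), "time_ms": times}).to_csv(
        path, sep="\t", index=False
    )


def read_events_tsv(path, duration_ms: float | None = None,
                    dt_ms: float = 2.0, n_channels: int | None = None) -> EventSeries:
    df = pd.read_csv(path, sep="\t")
    n_ch = int(df["channel_id"].max()) + 1 if len(df) else 0
    if n_channels is not None:
        n_ch = max(n_ch, n_channels)
    stamps = [
        np.sort(df.loc[df["channel_id"] == k, "time_ms"].to_numpy(dtype=float))
        for k in range(n_ch)
    ]
    if duration_ms is None:
        duration_ms = float(df["time_ms"].max()) + dt_ms if len(df) else 0.0
    return EventSeries(timestamps_ms=stamps, duration_ms=duration_ms, dt_ms=dt_ms)


def write_coarse_h5(path, rec: CoarseRecord) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("signal", data=rec.signal, compression="gzip")
        d.attrs["dt_ms"] = rec.dt_ms
        d.attrs["gamma"] = rec.gamma
        d.attrs["pitch_um"] = rec.pitch


def read_coarse_h5(path) -> CoarseRecord:
    with h5py.File(path, "r") as f:
        d = f["signal"]
        return CoarseRecord(
            signal=d[...],
            dt_ms=float(d.attrs["dt_ms"]),
            gamma=float(d.attrs.get("gamma", np.nan)),
            pitch=float(d.attrs.get("pitch_um", np.nan)),
        )


def write_coarse_csv(path, rec: CoarseRecord) -> None:
    """Small-fixture CSV: one row per channel; dt in a header comment."""
    with open(path, "w") as fh:
        fh.write(f"# dt_ms={rec.dt_ms} gamma={rec.gamma} pitch_um={rec.pitch}\n")
        np.savetxt(fh, rec.signal, delimiter=",")


def read_coarse_csv(path) -> CoarseRecord:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in header)
        sig = np.loadtxt(fh, delimiter=",", ndmin=2)
    return CoarseRecord(
        signal=sig,
        dt_ms=float(meta["dt_ms"]),
        gamma=float(meta.get("gamma", "nan")),
        pitch=float(meta.get("pitch_um", "nan")),
    )


def write_raster_tsv(path, result) -> None:
    """(time_ms, neuron_id) rows of a sparse spike raster."""
    pd.DataFrame(
        {"time_ms": result.spike_times_ms, "neuron_id": result.spike_neurons}
    ).to_csv(path, sep="\t", index=False)


def write_topology_h5(path, topo: NetworkTopology, seed: int | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=topo.positions)
        f.create_dataset("indptr", data=topo.indptr)
        f.create_dataset("targets", data=topo.targets)
        f.create_dataset("weights", data=topo.weights)
        f.create_dataset("distances", data=topo.distances)
        f.attrs["box_size_um"] = topo.box_size
        f.attrs["sigma_um"] = topo.sigma
        f.attrs["d_max_um"] = topo.d_max
        if seed is not None:
            f.attrs["seed"] = seed


def read_topology_h5(path) -> NetworkTopology:
    with h5py.File(path, "r") as f:
        return NetworkTopology(
            positions=f["positions"][...],
            indptr=f["indptr"][...],
            targets=f["targets"][...],
            weights=f["weights"][...],
            distances=f["distances"][...],
            box_size=float(f.attrs["box_size_um"]),
            sigma=float(f.attrs["sigma_um"]),
            d_max=float(f.attrs["d_max_um"]),
        )


def write_topology_tsv(path, topo: NetworkTopology) -> None:
    """Small-fixture dump: (i, j, d_ij_um, w_ij) rows."""
    src = np.repeat(np.arange(topo.n_neurons), topo.degrees)
    pd.DataFrame(
        {
            "i": src,
            "j": topo.targets,
            "d_ij_um": topo.distances,
            "w_ij": topo.weights,
        }
    ).to_csv(path, sep="\t", index=False)
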