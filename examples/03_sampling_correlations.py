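"""Spurious correlations from measurement overlap under coarse-sampling.

Uncorrelated Poisson dynamics are recorded by an 8x8 electrode array
(d_E = 400 um) both as LFP-like coarse signals and as spike sub-samples.
After thresholding and binning at 8 ms, adjacent coarse channels are
positively correlated although the neurons are independent; spike channels
are not.
"""

import numpy as np

from avasamp import (
    GeometryConfig,
    EventSeries,
    ThresholdSpec,
    adjacent_pairs,
    bandpass,
    build_connectivity,
    channel_correlation,
    coarse_signal,
    connection_radius,
    extract_events,
    named_state,
    place_electrodes,
    place_neurons,
    simulate,
    subsample_spikes,
)

N, STEPS, DT_BIN = 10_000, 100_000, 8.0

cfg0 = GeometryConfig(n_neurons=N, seed=3)
L = cfg0.system_size
array = place_electrodes((8, 8), 400.0, L)
cfg = GeometryConfig(n_neurons=N, seed=3, electrode_positions=array.positions)
pos = place_neurons(cfg)
topo = build_connectivity(pos, connection_radius(1000, cfg.density), 300.0, L)
res = simulate(topo, named_state("poisson"), STEPS, seed=4)

rec = coarse_signal(res, pos, array, L)
filt = bandpass(rec.signal, 0.1, 200.0, 500.0)
ev_coarse = extract_events(filt, ThresholdSpec(), 2.0)
ev_spikes = EventSeries.from_spike_record(subsample_spikes(res, pos, array, L))


def mean_adjacent_r(ev):
    n_bins = int(np.ceil(ev.duration_ms / DT_BIN))
    counts = np.stack([
        np.bincount(np.floor(t / DT_BIN).astype(int), minlength=n_bins)
        for t in ev.timestamps_ms
    ])
    rs = [
        channel_correlation(counts[a], counts[b])
        for a, b in adjacent_pairs(array)
        if counts[a].std() > 0 and counts[b].std() > 0
    ]
    return np.mean(rs)


print(f"Poisson dynamics, d_E = 400 um, bin = {DT_BIN:g} ms")
print(f"  mean adjacent-channel r, coarse: {mean_adjacent_r(ev_coarse):+.3f}")
print(f"  mean adjacent-channel r, spikes: {mean_adjacent_r(ev_spikes):+.3f}")
# The coarse value is clearly positive (shared field of view of nearby
# electrodes); the spike value sits at zero because each electrode observes
# a single, independent neuron.
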