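"""Build the spatial network and inspect its geometry.

Places neurons at the canonical density (100 / mm^2) on a periodic square,
connects every neuron to its neighbours within d_max with Gaussian
distance-decaying weights, and prints the resulting degree and weight
statistics.
"""

import numpy as np

from avasamp import (
    GeometryConfig,
    build_connectivity,
    connection_radius,
    place_neurons,
    system_size,
)

# Full-scale geometry is N = 160 000 neurons in a 4 cm box; here we use a
# 10 000-neuron patch at the same density so the script runs in seconds.
cfg = GeometryConfig(n_neurons=10_000, inter_neuron_distance=50.0, seed=1)
print(f"system size L = {cfg.system_size / 1e4:.2f} cm "
      f"(full scale: {system_size(160_000, 50.0) / 1e4:.0f} cm)")
print(f"density rho  = {cfg.density * 1e6:.0f} neurons / mm^2")

pos = place_neurons(cfg)
d_max = connection_radius(1000, cfg.density)
print(f"d_max for K = 1000: {d_max / 1000:.2f} mm")

topo = build_connectivity(pos, d_max, sigma=300.0, box_size=cfg.system_size)
print(f"mean out-degree: {topo.mean_degree:.0f} (target 1000)")

w_sums = np.bincount(
    np.repeat(np.arange(topo.n_neurons), topo.degrees),
    weights=topo.weights, minlength=topo.n_neurons,
)
print(f"max |sum_j w_ij - 1| = {np.abs(w_sums - 1).max():.2e}")
# Each row of weights is normalised to 1: the branching parameter m alone
# controls the expected number of offspring per spike.
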