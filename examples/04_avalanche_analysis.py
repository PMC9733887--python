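"""Avalanche-size distributions: coarse-sampling vs sub-sampling.

Runs the reverberating state (m = 0.98, close to critical but not at it),
samples it both ways, and fits the avalanche-size distribution with the
discrete truncated power law p(S) ~ S^-alpha on S in [1, 50].  Under
coarse-sampling the fit lands near alpha = 1.5 — the signature of a
critical branching process — although the dynamics are not critical; the
sub-sampled distribution decays visibly faster.
"""

from dataclasses import replace

from avasamp import avalanches as av
from avasamp.pipeline import preset, run_network

cfg = replace(
    preset("reverberating_desk"),
    n_networks=1,
    master_seed=42,
    bin_sizes_ms=(8.0,),
)
net = run_network(cfg, *cfg.network_seeds()[0])

print(f"tau_hat = {net.tau_hat_ms:.1f} ms (analytic 98.9 ms), "
      f"rate = {net.mean_rate_hz:.2f} Hz")
for path, sizes in (("coarse", net.sizes_coarse[8.0]),
                    ("spikes", net.sizes_spikes[8.0])):
    fit = av.fit_power_law(sizes)
    print(f"  {path}: {len(sizes)} avalanches, alpha = {fit.alpha:.2f} "
          f"(KS {fit.ks_distance:.3f})")
print(f"  m_av (coarse, 8 ms bins) = {net.m_av_coarse[8.0]:.2f} "
      "-- reads as 'critical' although m = 0.98")
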