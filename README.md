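# avasamp

Simulation and analysis of neuronal avalanches under realistic sampling:
a locally-connected branching network of binary neurons, recorded by a grid
of virtual electrodes either as LFP-like **coarse-sampled** signals or as
single-unit **sub-sampled** spikes, followed by the standard avalanche
pipeline (filtering, thresholding, binning, discrete power-law fits,
branching-parameter estimation).

## Why

Power-law avalanche-size distributions, `p(S) ~ S^-alpha` with
`alpha = 1.5`, are the classic signature of a critical branching process,
and they are reported ubiquitously from coarse measures (LFP, EEG, MEG)
while spike-based studies of awake cortex usually find subcritical-looking
distributions instead.  `avasamp` lets you generate ground-truth dynamics
at a *known* distance to criticality and then measure them both ways, to
quantify how much of an observed "signature of criticality" is produced by
the measurement itself: nearby electrodes share a field of view
(*measurement overlap*), which injects spurious inter-channel correlations,
and together with thresholding and temporal binning this can collapse the
avalanche statistics of subcritical, reverberating and critical dynamics
onto the same apparent power law — while spike sub-sampling keeps the
states distinguishable.

The package is aimed at people analysing multielectrode avalanche data or
studying criticality inference: the analysis half (`events`, `avalanches`)
reads plain `(channel_id, time_ms)` event tables and channel x time
matrices, so it applies to real recordings as well as to the bundled model.

## The model in brief

* `N` binary neurons, uniform on a periodic square at density
  `rho = 1/(4 d_N^2)` (d_N = 50 um, 100 / mm^2), connected to all
  neighbours within `d_max = sqrt(K / pi rho)` (mean degree K = 1000) with
  Gaussian distance-decaying weights (`sigma` = 300 um), normalised per
  neuron.
* Branching dynamics with drive: an active neuron activates target `j`
  with probability `m w_ij`; spontaneous spikes with probability `h` per
  neuron per step (`dt` = 2 ms); rate fixed at
  `r = h/(dt (1-m))` = 1 Hz.  The branching parameter `m` sets the
  intrinsic timescale `tau = -dt/ln(m)`: the canonical states are Poisson
  (m = 0), subcritical (0.9), reverberating (0.98) and near-critical
  (0.999).  Coalescence (simultaneous hits on one target) is compensated by
  redirecting to the next quiescent neuron in the source's distance-sorted
  target list.
* Virtual 8 x 8 electrode array with pitch `d_E`:
  coarse signal `V_k(t) = sum_i s_i(t)/d_ik^gamma` (all neurons, gamma = 1
  by default) and, per electrode, the spike train of its closest neuron.
* Pipeline: band-pass 0.1–200 Hz, events at the largest maximum of each
  supra-threshold (3 SD) positive excursion, binning at `dt_bin`,
  avalanches as maximal runs of non-empty bins, discrete truncated MLE
  power-law fits on S in [1, 50], bin-size scaling `alpha ~ dt_bin^-beta`,
  and the avalanche branching estimate `m_av` (average ratio of event
  counts in consecutive bins during non-zero activity).

## Worked example

```python
from dataclasses import replace
from avasamp import avalanches as av
from avasamp.pipeline import preset, run_network

cfg = replace(preset("reverberating_desk"), n_networks=1, master_seed=42,
              bin_sizes_ms=(8.0,))
net = run_network(cfg, *cfg.network_seeds()[0])
print(net.tau_hat_ms, net.mean_rate_hz)
for path, sizes in (("coarse", net.sizes_coarse[8.0]),
                    ("spikes", net.sizes_spikes[8.0])):
    fit = av.fit_power_law(sizes)
    print(path, len(sizes), fit.alpha)
print(net.m_av_coarse[8.0])
```

This simulates one desk-scale reverberating network (N = 25 600, m = 0.98,
2e5 steps), samples it with an 8 x 8 array at d_E = 400 um and runs the
avalanche analysis at 8 ms bins.  Formatted as in
`examples/04_avalanche_analysis.py`, the run prints:

```
tau_hat = 101.8 ms (analytic 98.9 ms), rate = 1.02 Hz
  coarse: 3485 avalanches, alpha = 1.46 (KS 0.007)
  spikes: 4694 avalanches, alpha = 1.62 (KS 0.033)
  m_av (coarse, 8 ms bins) = 0.97 -- reads as 'critical' although m = 0.98
```

Reading: the measured timescale matches the analytic value for m = 0.98 —
the dynamics are demonstrably *not* critical — yet the coarse-sampled
avalanche distribution fits a power law with `alpha ~ 1.5` and the
avalanche branching estimate sits at 1, both textbook signatures of
criticality.  The spike-sampled exponent is visibly steeper: sub-sampling
preserves the distinction.  The `examples/` directory walks through each
capability (network construction, the four states and their timescales,
spurious correlations, bin-size scaling, the inter-electrode-distance bias
of `m_av`); each script prints what it computes and what the numbers mean.

A thin CLI mirrors the pipeline stages (`avasamp simulate / analyze /
sweep / run / reproduce-figure`); see `avasamp --help`.

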