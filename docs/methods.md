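# Methods

## The model

`avasamp` simulates a two-level system: an underlying network of binary
neurons driven as a branching process, and a virtual measurement layer that
records that network the way an electrode array would.  The point of the
package is the *measurement* layer — the same ground-truth dynamics can be
read out as LFP-like coarse signals or as single-unit spikes, and the two
read-outs support very different conclusions about the dynamics.

### Network

`N` neurons are placed uniformly at random on a periodic square.  The mean
nearest-neighbour spacing `d_N` (default 50 um) sets the scale: for a 2D
Poisson process the linear size is `L = 2 sqrt(N) d_N` and the density
`rho = 1/(4 d_N^2)` = 100 / mm^2.  Every neuron connects to all neighbours
within a hard cutoff `d_max = sqrt(K / pi rho)` chosen so the mean
out-degree is `K` (1000 at full scale).  Connection weights decay as a
Gaussian of the periodic (minimum-image) distance with effective length
`sigma` = 300 um = 6 `d_N` and are normalised to sum to 1 per source, so
activity spreading is local and the branching parameter alone controls the
offspring budget.  Distance ties in the per-neuron sorted target lists are
broken by neuron index, giving the coalescence fallback (below) a total
order to walk.

### Dynamics

Time advances in steps of `dt` = 2 ms.  An active neuron activates each
target `j` with probability `m * w_ij`; every neuron additionally spikes
spontaneously with probability `h` per step and returns to quiescence
unless re-activated.  Stationarity fixes the per-neuron rate at
`r = h / (dt (1 - m))`; all four canonical states (`m` = 0, 0.9, 0.98,
0.999) use the `h` that yields 1 Hz, so comparisons between states carry no
rate confound.  The intrinsic timescale is `tau = -dt / ln(m)`.

Because spreading is local, simultaneous activations of a shared target
(coalescence) would silently reduce the effective branching parameter.
Compensation: when a successful activation lands on a neuron already marked
to spike, the next *quiescent* neuron in the source's distance-sorted
target list is activated instead (wrapping once past the end of the list;
if no quiescent target exists the activation is dropped).  Within one step,
recurrent activations are processed first — active sources in index order,
each source's targets in distance order — and spontaneous spikes are added
afterwards without compensation; a neuron marked by both is simply active.
The ordering is unobservable except through the compensation fallback, and
this fixed order makes runs bit-reproducible under a seed.

Even with compensation a residual coalescence bias remains in the
near-critical state: the measured timescale of the `m` = 0.999 state falls
short of the analytic 1.99 s (at full scale it measures about 1.6 s) and
the shortfall grows as the system shrinks.  Desk-scale near-critical runs
therefore show large run-to-run variance in both rate and timescale; this
is a property of the state, not an implementation artefact.

The production simulator (`simulate`) does not draw one Bernoulli variate
per connection.  Since the per-row activation probabilities are
non-increasing along the distance-sorted target list, the first success of
the remaining list can be located with a geometric skip under an envelope
equal to the probability at the current position, followed by an acceptance
test — exact thinning, identical in law to the naive per-target update
(`step`, kept as the executable reference) at O(m) expected draws per
active neuron instead of O(K).  The inner loop is JIT-compiled with numba.
Spontaneous spikes are drawn as a Binomial(N, h) count followed by a
partial Fisher–Yates sample of distinct indices.

Runs start all-quiescent and discard a burn-in of max(1000 steps,
10 tau/dt).  Saturation (every neuron active) is flagged, not fatal, so
near-critical scaled-down runs complete.  The AR(1) timescale estimator
fits `A(t+1) = b A(t) + c` by ordinary least squares over the post-burn-in
population activity and reports `tau_hat = -dt / ln(b)`; non-positive
slopes map to 0 (with a warning) since white noise has no timescale.

### Measurement layer

An 8 x 8 grid of point-like electrodes with pitch `d_E` is centred in the
box.  Neuron placement happens *after* electrode placement and rejects
positions within the 10 um dead zone around any electrode, which bounds the
coarse contributions.  Each electrode yields:

* coarse signal `V_k(t) = sum_i s_i(t) / d_ik^gamma` over *all* neurons,
  with minimum-image distances; `gamma` = 1 is a wide field of view (the
  default, strongest measurement overlap), `gamma` = 2 a narrow one.
  Contributions are instantaneous and strictly positive.
* spike channel: the timestamps of the single neuron closest to the
  electrode (ties by lowest index), all other neurons ignored.

### Event extraction and avalanches

Coarse signals are band-pass filtered 0.1–200 Hz (4th-order Butterworth in
second-order sections, applied forward-backward so event times are not
phase-shifted; the family/order/phase are not dictated by the procedure
being emulated and are exposed in `ThresholdSpec`).  Per channel, one event
is placed per positive excursion — at the single largest maximum between
two zero crossings of the demeaned trace — if that maximum exceeds 3
standard deviations of the full filtered trace.  Excursions truncated by
the record edge are kept only when their maximum is interior.  Spike
channels need no extraction.  From here both paths share one
representation: per-channel event timestamps.

Events from all channels are binned at `dt_bin` (anchored at t = 0) and
summed; an avalanche is a maximal run of non-empty bins bounded by empty
bins, with size S (total events) and duration D (bins).  Runs still open at
the record edges have undefined S and D and are discarded by default, with
their event counts reported so conservation (sum of S + discarded = total)
is checkable; `discard_edges=False` treats the edges as boundaries instead.

### Estimators

* **Power-law fit**: discrete maximum likelihood on the bounded integer
  support `[s_min, s_max]` (default [1, 50], mirroring the standard
  "fit range S <= 50"), normalised by the truncated zeta sum and maximised
  by bounded scalar search.  Fixed-range truncated MLE is used instead of
  automated lower-cutoff selection because the bounded support is part of
  the procedure being emulated; a KS distance between the empirical and
  fitted CDFs is reported as a diagnostic, and fits driven to the search
  boundary (e.g. all sizes equal) are flagged degenerate.  The sampler used
  in tests draws from the exact pmf by inverse CDF, so fits are checked
  against a ground truth generated independently of the fitting code.
* **Bin-size scaling**: `beta = -slope` of ln(alpha) against ln(dt_bin)
  over at least three bin sizes.
* **Avalanche branching estimate** `m_av`: the average ratio of event
  counts in consecutive bins during non-zero activity.  The default is the
  count-weighted ratio `sum(n_{b+1}) / sum(n_b)` over in-avalanche bin
  pairs — the consistent estimate of descendants-per-event, and the
  convention under which a coarse-sampled sweet spot reads `m_av ~ 1`
  (about 0.97–1.01 at `d_E` = 400 um, 8 ms bins, and at `d_E` = 250 um,
  4 ms bins, in desk-scale reverberating runs).  The unweighted mean of
  per-pair ratios ("pooled") and a per-avalanche average are available as
  options; note the unweighted mean is upward-biased for small counts
  (pairs (1,2) and (2,1) average to 1.25) and sits near 1.7–2.8 on the
  same data.

## Synthetic fixtures

`avasamp.synthetic` generates the controlled inputs the estimators are
validated on: AR(1) traces with Poisson innovations (known timescale,
mimicking drive `N h`), truncated discrete power-law samples (known
exponent), and independent Bernoulli event trains (zero-correlation
baseline).  These mimic the *statistical* structure of the model's outputs,
not real recordings: no measurement noise, no drift, no 1/f background, no
electrode artefacts.  Tests that pass on them validate the estimators'
correctness, not their robustness to real-data pathologies.

## Problem sizes

Full-scale parametrisation is N = 160 000 neurons (L = 4 cm), 10^6 steps
and 50 networks per condition.  The package's desk presets and test suite
run reduced versions that preserve density, `sigma`, `K` and the electrode
geometry — the ingredients of the local spreading and of measurement
overlap — while shrinking N to 10 000–25 600 (L = 1–1.6 cm), records to
1–2 x 10^5 steps and ensembles to 2–5 networks.  Consequences to keep in
mind:

* quantities tied to local dynamics (stationary rate, subcritical and
  reverberating timescales, coarse-sampled exponents at `d_E` = 400 um)
  reproduce well;
* the near-critical state suffers more coalescence bias and finite-size
  fluctuation, so its measured timescale and rate scatter widely;
* the far-field common-mode component of the coarse signal grows with L,
  so overlap-driven effects (spurious correlations, the `d_E` dependence of
  `m_av`) are present but compressed relative to full scale.  The `d_E`
  sweep therefore uses a paired design — one simulation per seed,
  re-sampled by all three arrays, with neuron placement avoiding the union
  of their dead zones — which removes network-to-network noise from the
  comparison.  Even so, the count-weighted `m_av` resolves the pitch
  dependence only partially at desk scale: the sweet spot reads ~1 and the
  dense 100 um array reads above 1, but at `d_E` = 500 um the weighted
  estimate sits at 1 within measurement noise (roughly 1.00 +/- 0.01 over
  paired seeds at N = 25 600, and flat at N = 57 600) instead of clearly
  below it — the subcritical-looking reading of sparse arrays needs the
  full-scale far field.  The *unweighted* per-pair-ratio convention, by
  contrast, shows the monotone pitch dependence robustly at desk scale
  (about 2.8 at 100 um down to 1.7 at 500 um) because its small-count bias
  amplifies with the changing avalanche-profile shape, at the price of
  never reading ~1 anywhere.

## Numerical choices and degenerate inputs

* Minimum-image distances everywhere; `d_max < L/2` is enforced.
* Weight normalisation is exact up to float accumulation (< 1e-12).
* `estimate_timescale` rejects constant series; slopes outside (0, 1) map
  to 0 or inf with warnings rather than complex timescales.
* `fit_power_law` requires at least 100 in-range samples (configurable)
  and raises `InsufficientData` carrying the observed count.
* `m_av` is undefined without a duration >= 2 avalanche and raises.
* Empty rasters, empty channels and all-zero bin vectors flow through the
  pipeline as empty results, not errors.
* Spike buffers are preallocated at 3x the expected stationary count; a
  run that exceeds them (runaway activity) is truncated and flagged.

## Known limitations

* The coarse signal is a bare 1/d^gamma sum — no neuron morphology, tissue
  filtering, dipole geometry or synaptic low-pass; it is the minimal model
  of a shared field of view, not an LFP model.
* No inhibition, refractoriness beyond the one-step reset, conduction
  delays, or plasticity.
* Only the AR(1) population-activity fit is provided for timescale
  estimation; subsampling-invariant multistep estimators are out of scope.
* The scaling-relation/shape-collapse analysis of avalanche size versus
  duration is out of scope (duration distributions themselves are
  computed).
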