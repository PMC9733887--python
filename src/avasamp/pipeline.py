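"""End-to-end experiment driver: config -> ensemble -> aggregated analysis.

A single :class:`ExperimentConfig` fixes geometry, dynamic state, electrode
settings and analysis parameters; :func:`run_experiment` then simulates an
ensemble of independent networks (per-network seeds split from the master
seed), samples each with both read-outs, extracts events, and aggregates
avalanche statistics (avalanches pooled across networks before
normalising).  Named presets carry the canonical parametrisations at full
scale and as ``*_desk`` variants sized for a single workstation.
"""

from __future__ import annotations

import hashlib
import logging
import traceback
from dataclasses import asdict, dataclass, replace

import numpy as np
import yaml

from . import avalanches as av
from . import dynamics, events, sampling, topology

logger = logging.getLogger("avasamp")

__all__ = ["ExperimentConfig", "ExperimentResult", "preset", "run_experiment",
           "PRESET_NAMES"]


@dataclass
class ExperimentConfig:
    """Fully serialisable description of one experiment.

    A config plus the code version determines every output; all lengths in
    um, times in ms.
    """

    name: str = "custom"
    # geometry
    n_neurons: int = 160_000
    d_n_um: float = 50.0
    k_mean: float = 1000.0
    sigma_um: float = 300.0
    # dynamics
    state: str = "reverberating"  # one of NAMED_STATES
    dt_ms: float = 2.0
    rate_hz: float = 1.0
    n_steps: int = 1_000_000
    # electrodes
    grid: tuple[int, int] = (8, 8)
    d_e_um: float = 400.0
    gamma: float = 1.0
    dead_zone_um: float = 10.0
    # analysis
    bin_sizes_ms: tuple[float, ...] = (2.0, 4.0, 8.0, 16.0)
    corr_bin_ms: float = 8.0
    threshold_multiplier: float = 3.0
    band_hz: tuple[float, float] = (0.1, 200.0)
    fit_s_min: int = 1
    fit_s_max: int = 50
    # ensemble
    n_networks: int = 50
    master_seed: int = 0

    @property
    def system_size_um(self) -> float:
        return topology.system_size(self.n_neurons, self.d_n_um)

    @property
    def density_per_um2(self) -> float:
        return 1.0 / (4.0 * self.d_n_um ** 2)

    @property
    def d_max_um(self) -> float:
        return topology.connection_radius(self.k_mean, self.density_per_um2)

    def dynamic_state(self) -> dynamics.DynamicState:
        return dynamics.DynamicState.from_rate(
            self.state, dynamics.NAMED_STATES[self.state].m, self.rate_hz,
            self.dt_ms,
        )

    def to_yaml(self) -> str:
        d = asdict(self)
        d["grid"] = list(d["grid"])
        d["bin_sizes_ms"] = list(d["bin_sizes_ms"])
        d["band_hz"] = list(d["band_hz"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        d = yaml.safe_load(text)
        for key in ("grid", "bin_sizes_ms", "band_hz"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha1(self.to_yaml().encode()).hexdigest()[:12]

    def network_seeds(self) -> list[tuple[int, int]]:
        """(topology_seed, dynamics_seed) per network, split from the master
        seed with numpy's SeedSequence so networks are independent."""
        children = np.random.SeedSequence(self.master_seed).spawn(self.n_networks)
        out = []
        for child in children:
            a, b = child.generate_state(2)
            out.append((int(a) & 0x7FFFFFFF, int(b) & 0x7FFFFFFF))
        return out


#: Desk-scale defaults: small enough for a single CPU, large enough that the
#: electrode array sits well inside the periodic box.
_DESK = dict(n_neurons=25_600, n_steps=200_000, n_networks=5)

PRESET_NAMES = tuple(
    list(dynamics.NAMED_STATES) + [f"{n}_desk" for n in dynamics.NAMED_STATES]
)


def preset(name: str) -> ExperimentConfig:
    """Named experiment configurations.

    ``poisson``/``subcritical``/``reverberating``/``critical`` are the
    full-scale parametrisations (N = 160 000 neurons, 10^6 steps, 50
    networks); the ``*_desk`` variants keep the density, sigma and all
    analysis settings but reduce N, steps and ensemble size to desk scale.
    """
    base = name.removesuffix("_desk")
    if base not in dynamics.NAMED_STATES:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    cfg = ExperimentConfig(name=name, state=base)
    if name.endswith("_desk"):
        cfg = replace(cfg, **_DESK)
    return cfg


@dataclass
class NetworkResult:
    """Per-network measurements (sizes kept so pooling can be redone)."""

    topology_seed: int
    dynamics_seed: int
    tau_hat_ms: float
    mean_rate_hz: float
    sizes_coarse: dict  # dt_bin_ms -> ndarray of S
    sizes_spikes: dict
    m_av_coarse: dict  # dt_bin_ms -> float (nan if undefined)
    m_av_spikes: dict
    corr_coarse: float  # mean adjacent-channel Pearson r (binned events)
    corr_spikes: float
    n_events_coarse: int
    n_events_spikes: int


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    config_hash: str
    networks: list[NetworkResult]
    failures: list[str]
    pooled_sizes_coarse: dict
    pooled_sizes_spikes: dict
    fits_coarse: dict  # dt_bin_ms -> PowerLawFit or None
    fits_spikes: dict

    @property
    def tau_hat_ms(self) -> float:
        return float(np.mean([n.tau_hat_ms for n in self.networks]))

    @property
    def mean_rate_hz(self) -> float:
        return float(np.mean([n.mean_rate_hz for n in self.networks]))

    def m_av(self, dt_bin_ms: float, path: str = "coarse") -> float:
        d = {"coarse": [n.m_av_coarse for n in self.networks],
             "spikes": [n.m_av_spikes for n in self.networks]}[path]
        vals = [x[dt_bin_ms] for x in d if np.isfinite(x.get(dt_bin_ms, np.nan))]
        return float(np.mean(vals)) if vals else float("nan")

    def bin_scaling(self, path: str = "coarse") -> av.BinScalingFit:
        fits = self.fits_coarse if path == "coarse" else self.fits_spikes
        pairs = [(dt, f.alpha) for dt, f in fits.items() if f is not None]
        return av.fit_bin_scaling(pairs)


def _binned_channel_counts(ev: events.EventSeries, dt_bin: float) -> np.ndarray:
    n_bins = max(int(np.ceil(ev.duration_ms / dt_bin)), 1)
    return np.stack(
        [
            np.bincount(
                np.floor(t / dt_bin).astype(np.int64), minlength=n_bins
            )
            for t in ev.timestamps_ms
        ]
    )


def _mean_adjacent_corr(
    ev: events.EventSeries, array: sampling.ElectrodeArray, dt_bin: float
) -> float:
    counts = _binned_channel_counts(ev, dt_bin)
    rs = []
    for a, b in sampling.adjacent_pairs(array):
        if counts[a].std() > 0 and counts[b].std() > 0:
            rs.append(sampling.channel_correlation(counts[a], counts[b]))
    return float(np.mean(rs)) if rs else float("nan")


def run_network(
    cfg: ExperimentConfig, topo_seed: int, dyn_seed: int
) -> NetworkResult:
    """Simulate, sample and analyse one network realisation."""
    L = cfg.system_size_um
    array = sampling.place_electrodes(
        cfg.grid, cfg.d_e_um, L, cfg.dead_zone_um, cfg.gamma
    )
    geo = topology.GeometryConfig(
        n_neurons=cfg.n_neurons,
        inter_neuron_distance=cfg.d_n_um,
        electrode_positions=array.positions,
        dead_zone_radius=cfg.dead_zone_um,
        seed=topo_seed,
    )
    pos = topology.place_neurons(geo)
    topo = topology.build_connectivity(pos, cfg.d_max_um, cfg.sigma_um, L)
    state = cfg.dynamic_state()
    res = dynamics.simulate(topo, state, cfg.n_steps, seed=dyn_seed)

    tau_hat = dynamics.estimate_timescale(res.activity, cfg.dt_ms)

    coarse = sampling.coarse_signal(res, pos, array, L)
    spec = events.ThresholdSpec(
        multiplier=cfg.threshold_multiplier,
        low_hz=cfg.band_hz[0],
        high_hz=cfg.band_hz[1],
    )
    fs = 1000.0 / cfg.dt_ms
    filtered = events.bandpass(coarse.signal, spec.low_hz, spec.high_hz, fs,
                               spec.order)
    ev_coarse = events.extract_events(filtered, spec, cfg.dt_ms)
    ev_spikes = events.EventSeries.from_spike_record(
        sampling.subsample_spikes(res, pos, array, L)
    )

    sizes_c, sizes_s, mav_c, mav_s = {}, {}, {}, {}
    for dt_bin in cfg.bin_sizes_ms:
        for ev, sizes, mav in (
            (ev_coarse, sizes_c, mav_c),
            (ev_spikes, sizes_s, mav_s),
        ):
            binned = av.bin_events(ev, dt_bin)
            avs = av.cut_avalanches(binned)
            sizes[dt_bin] = avs.sizes
            try:
                mav[dt_bin] = av.branching_from_avalanches(binned, avs)
            except ValueError:
                mav[dt_bin] = float("nan")

    return NetworkResult(
        topology_seed=topo_seed,
        dynamics_seed=dyn_seed,
        tau_hat_ms=tau_hat,
        mean_rate_hz=res.mean_rate_hz,
        sizes_coarse=sizes_c,
        sizes_spikes=sizes_s,
        m_av_coarse=mav_c,
        m_av_spikes=mav_s,
        corr_coarse=_mean_adjacent_corr(ev_coarse, array, cfg.corr_bin_ms),
        corr_spikes=_mean_adjacent_corr(ev_spikes, array, cfg.corr_bin_ms),
        n_events_coarse=ev_coarse.n_events,
        n_events_spikes=ev_spikes.n_events,
    )


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run the full ensemble and aggregate.

    Avalanches are pooled across networks before fitting; per-network
    results are kept so per-network aggregation can be recomputed.  A
    failed network run is logged and excluded (reported in ``failures``);
    the experiment only fails if every network does.
    """
    results: list[NetworkResult] = []
    failures: list[str] = []
    for i, (ts, ds) in enumerate(cfg.network_seeds()):
        try:
            logger.info(
                "network %d/%d (topology seed %d, dynamics seed %d)",
                i + 1, cfg.n_networks, ts, ds,
            )
            results.append(run_network(cfg, ts, ds))
        except Exception:
            msg = f"network {i} failed:\n{traceback.format_exc()}"
            logger.warning(msg)
            failures.append(msg)
    if not results:
        raise RuntimeError(f"all {cfg.n_networks} network runs failed")

    pooled_c, pooled_s, fits_c, fits_s = {}, {}, {}, {}
    for dt_bin in cfg.bin_sizes_ms:
        pooled_c[dt_bin] = np.concatenate(
            [n.sizes_coarse[dt_bin] for n in results]
        )
        pooled_s[dt_bin] = np.concatenate(
            [n.sizes_spikes[dt_bin] for n in results]
        )
        for pooled, fits in ((pooled_c, fits_c), (pooled_s, fits_s)):
            try:
                fits[dt_bin] = av.fit_power_law(
                    pooled[dt_bin], cfg.fit_s_min, cfg.fit_s_max
                )
            except av.InsufficientData:
                fits[dt_bin] = None

    return ExperimentResult(
        config=cfg,
        config_hash=cfg.config_hash(),
        networks=results,
        failures=failures,
        pooled_sizes_coarse=pooled_c,
        pooled_sizes_spikes=pooled_s,
        fits_coarse=fits_c,
        fits_spikes=fits_s,
    )
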