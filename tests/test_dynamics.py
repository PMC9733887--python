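"""Branching dynamics, analytic state relations, timescale estimation."""

import numpy as np
import pytest

from avasamp.dynamics import (
    DynamicState,
    NAMED_STATES,
    analytic_timescale,
    drive_for_rate,
    estimate_timescale,
    named_state,
    simulate,
    step,
)
from avasamp.synthetic import ar1_activity


class TestAnalyticRelations:
    @pytest.mark.parametrize(
        "m, expected_ms, atol",
        [
            (0.9, 18.9, 0.1),  # printed to 0.1 ms
            (0.999, 1990.0, 10.0),  # printed as 1.99 s
            (0.0, 0.0, 1e-12),
        ],
    )
    def test_timescale_table_values(self, m, expected_ms, atol):
        assert analytic_timescale(m, 2.0) == pytest.approx(expected_ms, abs=atol)

    def test_timescale_rejects_supercritical(self):
        with pytest.raises(ValueError):
            analytic_timescale(1.0, 2.0)

    @pytest.mark.parametrize(
        "m, h",
        [(0.0, 2e-3), (0.9, 2e-4), (0.98, 4e-5), (0.999, 2e-6)],
    )
    def test_drive_for_unit_rate(self, m, h):
        # the four canonical states all sit at 1 Hz per neuron
        assert drive_for_rate(1.0, m, 2.0) == pytest.approx(h)
        assert NAMED_STATES and named_state(
            [k for k, v in NAMED_STATES.items() if v.m == m][0]
        ).h == pytest.approx(h)

    def test_drive_rejects_h_above_one(self):
        with pytest.raises(ValueError):
            drive_for_rate(1e6, 0.0, 2.0)

    def test_state_roundtrip_rate(self):
        st = DynamicState.from_rate("x", m=0.95, r_hz=2.5, dt_ms=1.0)
        assert st.rate_hz == pytest.approx(2.5)


class _AlwaysSucceedRNG:
    """Stub generator whose uniforms are 0, so every attempt succeeds."""

    def random(self, size=None):
        return np.zeros(size) if size is not None else 0.0


class TestStepSemantics:
    def test_m_zero_is_pure_drive(self, small_topology, rng):
        st = DynamicState(m=0.0, h=0.05)
        active = np.arange(50)
        counts = [len(step(active, small_topology, st, rng)) for _ in range(200)]
        # next actives ~ Binomial(N, h) regardless of the input set
        n, h = small_topology.n_neurons, 0.05
        se = np.sqrt(n * h * (1 - h) / 200)
        assert abs(np.mean(counts) - n * h) < 4 * se

    def test_single_spike_offspring_mean_is_m(self, small_topology, rng):
        # with h = 0 the expected offspring of one active neuron is m
        st = DynamicState(m=0.8, h=0.0)
        counts = [
            len(step(np.array([7]), small_topology, st, rng))
            for _ in range(3000)
        ]
        se = np.sqrt(np.var(counts) / len(counts))
        assert abs(np.mean(counts) - 0.8) < 3.5 * se

    def test_coalescence_redirects_to_next_quiescent(self):
        # sources 0 and 1 share nearest target 2; source 1 also reaches 4.
        # With an always-succeed RNG the second hit on 2 must redirect to
        # the next quiescent neuron in source 1's distance-sorted list.
        from avasamp.topology import build_connectivity

        pos = np.array(
            [[440.0, 500.0], [560.0, 500.0], [500.0, 500.0],
             [400.0, 550.0], [600.0, 550.0]]
        )
        topo = build_connectivity(pos, 80.0, 300.0, 1000.0)
        assert list(topo.targets_of(0)) == [2, 3]
        assert list(topo.targets_of(1)) == [2, 4]
        st = DynamicState(m=0.999, h=0.0)
        nxt = step(np.array([0, 1]), topo, st, _AlwaysSucceedRNG())
        # source 0 marks 2 and 3; source 1's hit on 2 redirects to 4,
        # its hit on 4 then redirects back to... nothing quiescent -> drop
        assert list(nxt) == [2, 3, 4]

    def test_coalescence_exhausted_list_drops_activation(self):
        # both sources see only neuron 2: one activation must be dropped
        from avasamp.topology import build_connectivity

        pos = np.array([[480.0, 500.0], [520.0, 500.0], [500.0, 500.0]])
        topo = build_connectivity(pos, 25.0, 300.0, 1000.0)
        assert list(topo.targets_of(0)) == [2]
        assert list(topo.targets_of(1)) == [2]
        st = DynamicState(m=0.999, h=0.0)
        nxt = step(np.array([0, 1]), topo, st, _AlwaysSucceedRNG())
        assert list(nxt) == [2]

    def test_absorbing_without_drive(self, small_topology, rng):
        st = DynamicState(m=0.9, h=0.0)
        assert len(step(np.array([], dtype=int), small_topology, st, rng)) == 0


class TestSimulate:
    def test_poisson_counts_binomial(self, small_topology):
        st = named_state("poisson")
        res = simulate(small_topology, st, 20_000, seed=5, burn_in=100)
        a = res.activity
        n, h = small_topology.n_neurons, st.h
        assert abs(a.mean() - n * h) < 4 * np.sqrt(n * h / len(a))
        # variance of Binomial(N, h)
        assert a.var() == pytest.approx(n * h * (1 - h), rel=0.2)

    def test_stationary_rate_subcritical(self, small_topology):
        st = named_state("subcritical")
        res = simulate(small_topology, st, 50_000, seed=6)
        se = _batch_se(res.activity) / (
            small_topology.n_neurons * st.dt_ms / 1000.0
        )
        assert abs(res.mean_rate_hz - 1.0) < 3 * se + 0.05

    def test_no_drive_empty_start_stays_silent(self, small_topology):
        st = DynamicState(m=0.9, h=0.0)
        res = simulate(small_topology, st, 1000, seed=0, burn_in=0)
        assert len(res.spike_steps) == 0

    def test_bit_identical_under_seed(self, small_topology):
        st = named_state("subcritical")
        r1 = simulate(small_topology, st, 5000, seed=42)
        r2 = simulate(small_topology, st, 5000, seed=42)
        assert np.array_equal(r1.spike_steps, r2.spike_steps)
        assert np.array_equal(r1.spike_neurons, r2.spike_neurons)

    def test_activity_consistent_with_raster(self, small_topology):
        res = simulate(small_topology, named_state("subcritical"), 2000, seed=3)
        a = res.activity
        assert a.sum() == len(res.spike_steps)
        assert a.max() <= small_topology.n_neurons

    def test_fast_kernel_matches_reference_offspring_rate(self, small_topology):
        # the thinned kernel and the naive reference must produce the same
        # stationary rate (both exact samplers of the same process)
        st = named_state("subcritical")
        res = simulate(small_topology, st, 30_000, seed=9)
        rng = np.random.default_rng(9)
        counts = []
        active = np.arange(0)
        for _ in range(3000):
            active = step(active, small_topology, st, rng)
            counts.append(len(active))
        mean_fast = res.activity.mean()
        mean_ref = np.mean(counts[500:])
        se = _batch_se(np.asarray(counts[500:], dtype=float))
        se_fast = _batch_se(res.activity.astype(float))
        assert abs(mean_fast - mean_ref) < 4 * np.hypot(se, se_fast)

    def test_compensation_restores_timescale(self, small_topology):
        # coalescence silently lowers the effective m; with compensation the
        # measured timescale must come closer to the analytic value
        st = named_state("reverberating")
        tau_on = estimate_timescale(
            simulate(small_topology, st, 60_000, seed=12).activity, st.dt_ms
        )
        tau_off = estimate_timescale(
            simulate(
                small_topology, st, 60_000, seed=12, compensate=False
            ).activity,
            st.dt_ms,
        )
        assert abs(tau_on - st.tau_ms) < abs(tau_off - st.tau_ms)


def _batch_se(x: np.ndarray, n_batches: int = 20) -> float:
    """Standard error of the mean from batch means (autocorrelation-safe)."""
    n = len(x) // n_batches
    means = x[: n * n_batches].reshape(n_batches, n).mean(axis=1)
    return means.std(ddof=1) / np.sqrt(n_batches)


class TestTimescaleEstimator:
    def test_recovers_known_ar1_timescale(self):
        # generator is its own oracle: slope e^(-2/19) -> tau = 19 ms
        a = ar1_activity(200_000, tau_ms=19.0, dt_ms=2.0, seed=8)
        assert estimate_timescale(a, 2.0) == pytest.approx(19.0, rel=0.02)

    def test_white_noise_has_no_timescale(self):
        a = ar1_activity(100_000, tau_ms=0.0, seed=9)
        tau = estimate_timescale(a, 2.0)
        assert tau < 0.5

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            estimate_timescale(np.full(100, 5.0), 2.0)
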