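"""Avalanche decomposition, distributions, power-law fits, m_av."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from avasamp.avalanches import (
    AvalancheSet,
    BinnedActivity,
    InsufficientData,
    bin_events,
    branching_from_avalanches,
    cut_avalanches,
    distribution_ks_distance,
    duration_distribution,
    fit_bin_scaling,
    fit_power_law,
    sample_power_law,
    size_distribution,
)
from avasamp.events import EventSeries
from avasamp.synthetic import power_law_sizes


def _events(times_by_channel, duration_ms, dt_ms=2.0):
    return EventSeries(
        timestamps_ms=[np.asarray(t, dtype=float) for t in times_by_channel],
        duration_ms=duration_ms,
        dt_ms=dt_ms,
    )


def _naive_cut(counts, discard_edges=True):
    """Reference avalanche decomposition: explicit scan of the bin vector."""
    counts = [int(c) for c in counts]
    runs, cur = [], []
    for c in counts:
        if c > 0:
            cur.append(c)
        elif cur:
            runs.append((cur, False))
            cur = []
    if cur:
        runs.append((cur, True))  # still open at the record end
    sizes, durs, discarded = [], [], 0
    for i, (r, open_end) in enumerate(runs):
        open_start = i == 0 and counts[0] > 0
        if discard_edges and (open_start or open_end):
            discarded += sum(r)
        else:
            sizes.append(sum(r))
            durs.append(len(r))
    return sizes, durs, discarded


class TestBinning:
    def test_documented_example(self):
        ev = _events([[1.0, 9.0], [3.0]], duration_ms=12.0)
        binned = bin_events(ev, 4.0)
        assert list(binned.counts) == [2, 0, 1]

    def test_empty_series_all_zero(self):
        ev = _events([[], []], duration_ms=40.0)
        assert bin_events(ev, 8.0).counts.sum() == 0

    def test_conservation(self, rng):
        times = np.sort(rng.uniform(0, 1000.0, 500))
        ev = _events([times[:250], times[250:]], duration_ms=1000.0)
        assert bin_events(ev, 7.0).total_events == 500

    def test_bin_edges_left_closed(self):
        ev = _events([[4.0]], duration_ms=8.0)
        assert list(bin_events(ev, 4.0).counts) == [0, 1]


class TestCutting:
    def test_documented_example_with_edge_boundaries(self):
        b = BinnedActivity(np.array([3, 1, 0, 2, 0, 0, 5]), 4.0)
        avs = cut_avalanches(b, discard_edges=False)
        assert sorted(avs.sizes) == [2, 4, 5]
        assert sorted(avs.durations) == [1, 1, 2]

    def test_edge_runs_discarded_by_default(self):
        b = BinnedActivity(np.array([3, 1, 0, 2, 0, 0, 5]), 4.0)
        avs = cut_avalanches(b)
        assert list(avs.sizes) == [2]
        assert avs.discarded_events == 9
        assert avs.sizes.sum() + avs.discarded_events == b.total_events

    def test_all_zero(self):
        assert cut_avalanches(BinnedActivity(np.zeros(10, int), 2.0)).n_avalanches == 0

    def test_all_occupied_single_spanning_run(self):
        b = BinnedActivity(np.array([1, 2, 3]), 2.0)
        avs = cut_avalanches(b, discard_edges=False)
        assert list(avs.sizes) == [6] and list(avs.durations) == [3]
        # under the default the spanning run is a truncated cascade
        assert cut_avalanches(b).n_avalanches == 0

    @pytest.mark.parametrize("discard", [True, False])
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(counts=st.lists(st.integers(min_value=0, max_value=5),
                           min_size=1, max_size=60))
    def test_matches_naive_reference(self, counts, discard):
        c = np.asarray(counts)
        avs = cut_avalanches(BinnedActivity(c, 2.0), discard_edges=discard)
        sizes, durs, discarded = _naive_cut(c, discard_edges=discard)
        assert list(avs.sizes) == sizes
        assert list(avs.durations) == durs
        assert avs.sizes.sum() + avs.discarded_events == c.sum()

    def test_matches_naive_on_many_random_vectors(self, rng):
        # bulk oracle check over 10^4 random count vectors
        for _ in range(10_000):
            c = rng.integers(0, 3, size=rng.integers(1, 30))
            avs = cut_avalanches(BinnedActivity(c, 2.0))
            sizes, durs, discarded = _naive_cut(c)
            assert list(avs.sizes) == sizes and list(avs.durations) == durs
            assert avs.discarded_events == discarded

    def test_bin_merge_monotonicity(self, rng):
        # doubling the bin size can only merge avalanches, never split
        times = np.sort(rng.uniform(0, 4000.0, 400))
        ev = _events([times], duration_ms=4000.0)
        n = [
            cut_avalanches(bin_events(ev, dt), discard_edges=False).n_avalanches
            for dt in (2.0, 4.0, 8.0, 16.0)
        ]
        assert n == sorted(n, reverse=True)


class TestDistributions:
    def test_size_distribution_example(self):
        avs = AvalancheSet(np.array([4, 2, 5]), np.array([2, 1, 1]), 4.0)
        s, p = size_distribution(avs)
        assert list(s) == [2, 4, 5]
        assert p == pytest.approx([1 / 3] * 3)

    def test_degenerate_single_avalanche(self):
        avs = AvalancheSet(np.array([7]), np.array([3]), 4.0)
        s, p = size_distribution(avs)
        assert list(s) == [7] and list(p) == [1.0]

    def test_duration_distribution_normalises(self):
        avs = AvalancheSet(np.array([4, 2, 5]), np.array([2, 1, 1]), 4.0)
        d, p = duration_distribution(avs)
        assert list(d) == [1, 2] and p == pytest.approx([2 / 3, 1 / 3])

    def test_empirical_matches_generator(self):
        # multinomial agreement between sampler and its exact pmf
        sizes = power_law_sizes(1.5, 10_000, seed=2)
        avs = AvalancheSet(sizes, np.ones_like(sizes), 2.0)
        s, p = size_distribution(avs)
        support = np.arange(1, 51)
        pmf = support ** -1.5 / (support ** -1.5).sum()
        for si, pi in zip(s, p):
            expect = pmf[si - 1]
            se = np.sqrt(expect * (1 - expect) / 10_000)
            assert abs(pi - expect) < 4 * se + 1e-4


class TestPowerLawFit:
    def test_recovers_exponent(self):
        sizes = power_law_sizes(1.5, 100_000, seed=3)
        fit = fit_power_law(sizes)
        assert fit.alpha == pytest.approx(1.5, abs=0.02)
        assert not fit.degenerate
        assert fit.ks_distance < 0.01

    @pytest.mark.parametrize("alpha", [1.0, 2.0, 3.0])
    def test_recovers_other_exponents(self, alpha):
        sizes = power_law_sizes(alpha, 50_000, seed=4)
        assert fit_power_law(sizes).alpha == pytest.approx(alpha, abs=0.05)

    def test_too_few_samples_error_carries_count(self):
        with pytest.raises(InsufficientData) as err:
            fit_power_law(np.array([1, 2, 3]))
        assert err.value.n == 3

    def test_degenerate_constant_sizes_flagged(self):
        fit = fit_power_law(np.full(500, 7))
        assert fit.degenerate

    def test_out_of_range_samples_excluded(self):
        sizes = np.concatenate([power_law_sizes(1.5, 5000, seed=5),
                                np.full(1000, 10_000)])
        fit = fit_power_law(sizes, 1, 50)
        assert fit.n == 5000


class TestBinScaling:
    def test_exact_noiseless_recovery(self):
        dts = np.array([2.0, 4.0, 8.0, 16.0])
        pairs = list(zip(dts, 2.0 * dts ** -0.16))
        assert fit_bin_scaling(pairs).beta == pytest.approx(0.16)

    def test_constant_alpha_gives_zero(self):
        pairs = [(2.0, 1.5), (4.0, 1.5), (8.0, 1.5)]
        assert fit_bin_scaling(pairs).beta == pytest.approx(0.0, abs=1e-12)

    def test_needs_three_bin_sizes(self):
        with pytest.raises(ValueError):
            fit_bin_scaling([(2.0, 1.5), (4.0, 1.4)])


class TestBranchingEstimate:
    def test_single_avalanche_doubling(self):
        b = BinnedActivity(np.array([0, 2, 4, 0]), 2.0)
        assert branching_from_avalanches(b) == pytest.approx(2.0)
        assert branching_from_avalanches(b, method="pooled") == pytest.approx(2.0)

    def test_flat_avalanches_give_unity(self):
        b = BinnedActivity(np.array([0, 1, 1, 1, 0, 2, 2, 0]), 2.0)
        assert branching_from_avalanches(b) == pytest.approx(1.0)
        assert branching_from_avalanches(b, method="pooled") == pytest.approx(1.0)

    def test_convention_differences_on_mixed_ratios(self):
        # avalanches [1,2] and [4,2]: pairwise ratios 2 and 0.5
        b = BinnedActivity(np.array([0, 1, 2, 0, 4, 2, 0]), 2.0)
        assert branching_from_avalanches(b, method="pooled") == pytest.approx(1.25)
        assert branching_from_avalanches(b, method="weighted") == pytest.approx(4 / 5)
        assert branching_from_avalanches(
            b, method="per_avalanche"
        ) == pytest.approx(1.25)

    def test_undefined_without_multibin_avalanche(self):
        with pytest.raises(ValueError):
            branching_from_avalanches(BinnedActivity(np.array([0, 3, 0, 1, 0]), 2.0))

    def test_recovers_subcritical_ratio_from_synthetic_cascades(self):
        # geometric decay counts: each bin carries ~0.7x the previous
        # (floored, so every cascade terminates at 0)
        counts = []
        for _ in range(400):
            n = 64
            while n > 0:
                counts.append(n)
                n = int(n * 0.7)
            counts.append(0)
        b = BinnedActivity(np.array(counts), 2.0)
        assert branching_from_avalanches(b) == pytest.approx(0.7, abs=0.05)


class TestKSDistance:
    def test_identical_samples_zero(self):
        s = np.array([1, 2, 2, 3, 5])
        assert distribution_ks_distance(s, s) == 0.0

    def test_disjoint_samples_one(self):
        assert distribution_ks_distance(np.ones(5), np.full(5, 9)) == 1.0

    def test_same_generator_small_distance(self):
        a = power_law_sizes(1.5, 20_000, seed=6)
        b = power_law_sizes(1.5, 20_000, seed=7)
        assert distribution_ks_distance(a, b) < 0.02
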