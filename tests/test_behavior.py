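"""Lick-burst microstructure and spike-burst metrics vs brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberphot import (
    epoch_firing_metrics,
    segment_lick_bursts,
    segment_spike_bursts,
    simulate_licks,
    simulate_spikes,
)
from fiberphot.errors import AnalysisError
from conftest import oracle_group_bursts, oracle_spike_bursts


class TestLickBursts:
    def test_empty_train(self):
        bs = segment_lick_bursts(np.array([]))
        assert bs.n_bursts == 0
        assert bs.n_events_total == 0

    def test_worked_example_two_bursts(self):
        bs = segment_lick_bursts(np.array([0.0, 0.1, 0.2, 1.0, 1.1]))
        assert bs.n_bursts == 2
        assert bs.burst_sizes.tolist() == [3, 2]
        assert bs.burst_bounds == ((0.0, 0.2), (1.0, 1.1))

    def test_slow_licking_yields_no_bursts(self):
        bs = segment_lick_bursts(np.array([0.0, 0.5, 1.0]))
        assert bs.n_bursts == 0
        assert bs.n_events_total == 3

    def test_interval_equal_to_threshold_splits(self):
        # strict inequality: an ILI of exactly 250 ms separates bursts
        bs = segment_lick_bursts(np.array([0.0, 0.25, 0.5]))
        assert bs.n_bursts == 0

    def test_matches_bruteforce_oracle_on_random_trains(self):
        rng = np.random.default_rng(99)
        for _ in range(300):
            n = int(rng.integers(0, 40))
            t = np.sort(rng.uniform(0, 10, size=n).round(3))
            bs = segment_lick_bursts(t)
            want = oracle_group_bursts(t, 0.25, 2)
            assert bs.n_bursts == len(want)
            for (b0, b1), size, grp in zip(bs.burst_bounds, bs.burst_sizes, want):
                assert b0 == pytest.approx(grp[0])
                assert b1 == pytest.approx(grp[-1])
                assert size == len(grp)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 30, size=60))
        counts = [segment_lick_bursts(t, thr).n_events_in_bursts
                  for thr in (0.1, 0.25, 0.5, 1.0)]
        assert counts == sorted(counts)

    def test_bursts_are_disjoint_partition(self):
        rng = np.random.default_rng(6)
        t = np.sort(rng.uniform(0, 20, size=80))
        bs = segment_lick_bursts(t)
        seen = set()
        for i0, i1 in bs.burst_slices:
            idx = set(range(i0, i1))
            assert not (idx & seen)
            seen |= idx

    def test_unsorted_input_rejected(self):
        with pytest.raises(AnalysisError):
            segment_lick_bursts(np.array([1.0, 0.5]))

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.floats(0.0, 30.0, allow_nan=False), max_size=50))
    def test_property_segmentation_equals_oracle(self, raw_times):
        t = np.sort(np.asarray(raw_times, dtype=float))
        bs = segment_lick_bursts(t)
        want = oracle_group_bursts(t, 0.25, 2)
        assert bs.burst_sizes.tolist() == [len(g) for g in want]
        # every within-burst gap strictly below the threshold
        for i0, i1 in bs.burst_slices:
            assert np.all(np.diff(t[i0:i1]) < 0.25)


class TestSpikeBursts:
    def test_worked_example(self):
        bs = segment_spike_bursts(np.array([0.0, 0.05, 0.10, 0.5, 1.0, 1.04]))
        assert bs.n_bursts == 2
        assert bs.burst_sizes.tolist() == [3, 2]
        assert bs.mean_size == 2.5
        assert bs.burst_bounds == ((0.0, 0.10), (1.0, 1.04))

    def test_regular_slow_train_has_no_bursts(self):
        t = np.arange(0, 100, 0.5)  # 2 Hz
        assert segment_spike_bursts(t).n_bursts == 0

    def test_empty_train(self):
        assert segment_spike_bursts(np.array([])).n_bursts == 0

    def test_burst_extends_at_offset_not_onset_isi(self):
        # ISI 0.1 s is >= onset (0.08) but < offset (0.16): it extends a
        # burst already opened, but cannot open one
        opened = segment_spike_bursts(np.array([0.0, 0.05, 0.15, 0.25]))
        assert opened.burst_sizes.tolist() == [4]
        not_opened = segment_spike_bursts(np.array([0.0, 0.1, 0.2]))
        assert not_opened.n_bursts == 0

    def test_matches_bruteforce_oracle_on_random_trains(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            n = int(rng.integers(0, 60))
            t = np.sort(rng.exponential(0.12, size=n).cumsum())
            bs = segment_spike_bursts(t)
            want = oracle_spike_bursts(t, 0.08, 0.16)
            assert bs.n_bursts == len(want)
            for size, grp in zip(bs.burst_sizes, want):
                assert size == len(grp)

    def test_every_burst_has_at_least_two_spikes(self):
        rng = np.random.default_rng(8)
        t = np.sort(rng.exponential(0.1, size=200).cumsum())
        bs = segment_spike_bursts(t)
        assert np.all(bs.burst_sizes >= 2)


class TestEpochMetrics:
    def test_uniform_two_hz_train(self):
        t = np.arange(0, 200, 0.5)
        stats = epoch_firing_metrics(t, (0.0, 200.0))
        assert stats.firing_rate_hz == pytest.approx(2.0)
        assert stats.bursting_rate_hz == 0.0
        assert stats.mean_spikes_per_burst is None

    def test_synthetic_bursty_train_recovers_burst_rate(self):
        times, members = simulate_spikes(
            duration_s=400.0, tonic_rate_hz=0.5, burst_rate_hz=0.1,
            spikes_per_burst=4, intra_burst_isi_s=0.04, seed=17)
        stats = epoch_firing_metrics(times, (0.0, 400.0))
        # Poisson SE of the burst count at rate 0.1/s over 400 s is ~0.016/s;
        # tonic spikes can merge into or extend bursts, so allow 4 SE
        assert stats.bursting_rate_hz == pytest.approx(0.1, abs=0.065)

    def test_empty_epoch_reports_absent_burst_size(self):
        stats = epoch_firing_metrics(np.array([500.0]), (0.0, 200.0))
        assert stats.firing_rate_hz == 0.0
        assert stats.bursting_rate_hz == 0.0
        assert stats.mean_spikes_per_burst is None

    def test_epoch_window_is_half_open(self):
        stats = epoch_firing_metrics(np.array([0.0, 200.0]), (0.0, 200.0))
        assert stats.n_spikes == 1

    def test_zero_duration_epoch_rejected(self):
        with pytest.raises(AnalysisError):
            epoch_firing_metrics(np.array([1.0]), (5.0, 5.0))


class TestLickSimulation:
    def test_zero_bursts_empty_train(self):
        assert simulate_licks(0, 3, seed=0).size == 0

    def test_drawn_sizes_recovered_by_segmentation(self):
        t = simulate_licks(2, [3, 2], intra_ili_s=0.1, inter_burst_gap_s=0.8, seed=4)
        bs = segment_lick_bursts(t)
        assert bs.burst_sizes.tolist() == [3, 2]
        # brute-force grouping oracle agrees
        assert [len(g) for g in oracle_group_bursts(t, 0.25, 2)] == [3, 2]

    def test_deterministic_under_seed(self):
        a = simulate_licks(5, 4, seed=11)
        b = simulate_licks(5, 4, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_gap_ordering_violation_rejected(self):
        from fiberphot.errors import ConfigError
        with pytest.raises(ConfigError):
            simulate_licks(2, 3, intra_ili_s=0.3, inter_burst_gap_s=0.8, seed=0)


class TestSpikeSimulation:
    def test_tonic_rate_recovered(self):
        times, _ = simulate_spikes(200.0, tonic_rate_hz=2.0, burst_rate_hz=0.0, seed=21)
        rate = times.size / 200.0
        assert rate == pytest.approx(2.0, abs=0.3)

    def test_all_rates_zero_empty_train(self):
        times, members = simulate_spikes(100.0, 0.0, 0.0, seed=0)
        assert times.size == 0
        assert members == []

    def test_deterministic_under_seed(self):
        a, _ = simulate_spikes(50.0, 1.0, 0.2, seed=33)
        b, _ = simulate_spikes(50.0, 1.0, 0.2, seed=33)
        np.testing.assert_array_equal(a, b)

    def test_negative_rate_rejected(self):
        from fiberphot.errors import ConfigError
        with pytest.raises(ConfigError):
            simulate_spikes(10.0, -1.0, 0.0, seed=0)

    def test_strictly_increasing_timestamps(self):
        times, _ = simulate_spikes(100.0, 3.0, 0.3, seed=2)
        assert np.all(np.diff(times) > 0)
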