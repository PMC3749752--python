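"""Event detection, binning, avalanche extraction, and power-law fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avacrit import (BinnedRaster, EventRaster, SignalMatrix, SizeDistribution,
                     avalanche_sizes, bin_events, detect_nlfps,
                     empirical_pattern_distribution, extract_avalanches,
                     fit_power_law, sample_discrete_powerlaw, segment_stability,
                     simulate_branching, BranchingSpec)


def _noise_signal(rng, n_channels=2, n_samples=5000):
    return SignalMatrix(rng.standard_normal((n_channels, n_samples)), 1000.0)


class TestDetect:
    def test_constant_channel_rejected(self):
        sig = SignalMatrix(np.vstack([np.random.default_rng(0).standard_normal(100),
                                      np.ones(100)]), 1000.0)
        with pytest.raises(ValueError, match="channel 1"):
            detect_nlfps(sig)

    def test_single_deflection_located_at_minimum(self):
        rng = np.random.default_rng(1)
        values = 0.1 * rng.standard_normal(2000)
        values[700:720] = -5.0 * values.std()  # one clean sub-threshold excursion
        values[710] -= 2.0  # unambiguous minimum
        sig = SignalMatrix(values[None, :], 1000.0)
        raster = detect_nlfps(sig, threshold_sd=-2.5)
        assert raster.n_events == 1
        assert raster.samples[0] == 710

    def test_detector_follows_negative_convention(self):
        """Sign-flipping the trace moves events to the former positive peaks."""
        rng = np.random.default_rng(2)
        values = rng.standard_normal(5000)
        down = detect_nlfps(SignalMatrix(values[None, :], 1000.0), -2.5)
        up = detect_nlfps(SignalMatrix(-values[None, :], 1000.0), -2.5)
        # events of the flipped trace sit where the original had maxima,
        # disjoint from the original minima
        assert set(down.samples).isdisjoint(up.samples)
        assert np.all(values[up.samples] > 0)

    def test_positive_threshold_rejected(self, rng):
        with pytest.raises(ValueError):
            detect_nlfps(_noise_signal(rng), 2.5)

    def test_one_event_per_excursion(self):
        # two separate dips -> two events; a double-trough single excursion -> one
        base = np.zeros(300)
        base[:50] = np.sin(np.arange(50))  # give the trace nonzero SD
        base[100:105] = -10.0
        base[200:205] = -10.0
        raster = detect_nlfps(SignalMatrix(base[None, :], 1000.0), -2.5)
        assert raster.n_events == 2
        # ties within an excursion resolve to the earliest sample
        assert raster.samples[0] == 100 and raster.samples[1] == 200


class TestBinning:
    def test_floor_convention(self):
        # events at 0.1 ms and 1.9 ms with dt=2 share bin 0; 2.0 ms -> bin 1
        raster = EventRaster([0, 0, 0], [1, 19, 20], 1, 10_000.0)
        binned = bin_events(raster, 2.0)
        assert binned.occupancy[0, 0] and binned.occupancy[0, 1]
        assert binned.occupancy.sum() == 2

    def test_empty_raster(self):
        binned = bin_events(EventRaster([], [], 3, 1000.0, n_samples=100), 2.0)
        assert not binned.occupancy.any()
        assert binned.n_bins == 50


class TestExtraction:
    def test_hand_traced_example(self):
        occ = np.zeros((3, 4), dtype=bool)
        occ[0, 0] = True            # bin 0: ch0
        occ[1, 1] = occ[2, 1] = True  # bin 1: ch1, ch2
        occ[0, 3] = True            # bin 3: ch0 (bin 2 empty)
        avs = extract_avalanches(BinnedRaster(occ, 2.0))
        assert [a.size for a in avs] == [3, 1]
        assert avs[0].start_bin == 0 and avs[0].duration_bins == 2
        assert list(avs[0].pattern) == [1, 1, 1]
        assert list(avs[1].pattern) == [1, -1, -1]

    def test_fully_occupied_is_single_avalanche(self):
        raster = BinnedRaster(np.ones((2, 10), dtype=bool), 1.0)
        avs = extract_avalanches(raster)
        assert len(avs) == 1 and avs[0].size == 20

    def test_empty_raster(self):
        assert extract_avalanches(BinnedRaster(np.zeros((2, 5), dtype=bool), 1.0)) == []

    @staticmethod
    def _scan_oracle(occ):
        """Naive single-pass scan: independent reference implementation."""
        sizes, current = [], 0
        for b in range(occ.shape[1]):
            count = int(occ[:, b].sum())
            if count:
                current += count
            elif current:
                sizes.append(current)
                current = 0
        if current:
            sizes.append(current)
        return sizes

    @given(st.integers(0, 2**64 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_scan_oracle_and_conserves_events(self, seed):
        rng = np.random.default_rng(seed)
        occ = rng.random((rng.integers(1, 9), rng.integers(1, 51))) < rng.uniform(0.05, 0.6)
        raster = BinnedRaster(occ, 1.0)
        avs = extract_avalanches(raster)
        assert [a.size for a in avs] == self._scan_oracle(occ)
        assert sum(a.size for a in avs) == occ.sum()
        assert list(avalanche_sizes(raster)) == [a.size for a in avs]
        for a in avs:
            # every bin inside an avalanche is occupied; pattern marks rows
            assert a.events.any(axis=0).all()
            assert np.array_equal(a.pattern == 1, a.events.any(axis=1))


class TestPatternDistribution:
    def test_full_set_has_no_quiescent_mass(self):
        occ = np.random.default_rng(0).random((4, 200)) < 0.2
        avs = extract_avalanches(BinnedRaster(occ, 1.0))
        dist = empirical_pattern_distribution(avs, range(4))
        assert dist.p0 == 0.0

    def test_hand_counted_projection(self):
        occ = np.zeros((2, 3), dtype=bool)
        occ[0, 0] = True  # avalanche on ch0
        occ[1, 2] = True  # avalanche on ch1
        avs = extract_avalanches(BinnedRaster(occ, 1.0))
        dist = empirical_pattern_distribution(avs, [0])
        assert dist.p0 == 0.5  # the ch1-only avalanche projects to quiescent

    def test_quiescent_probability_nonincreasing_in_subset_size(self):
        sizes, raster = simulate_branching(BranchingSpec(12, 1.0, 2000, seed=21))
        avs = extract_avalanches(raster)
        p0 = [empirical_pattern_distribution(avs, range(n)).p0 for n in range(1, 9)]
        assert all(a >= b for a, b in zip(p0, p0[1:]))


class TestPowerLawFit:
    def test_self_fit_is_exact(self):
        s = np.arange(1, 101)
        pmf = s**-1.5 / (s**-1.5).sum()
        dist = SizeDistribution(s, pmf, 0)
        fit = fit_power_law(dist)
        assert abs(fit.exponent - (-1.5)) < 1e-6
        assert fit.ks_distance < 1e-10

    def test_sample_recovery(self):
        samples = sample_discrete_powerlaw(-1.5, 100, 100_000, seed=3)
        fit = fit_power_law(samples)
        assert abs(fit.exponent - (-1.5)) < 0.05

    def test_fixed_exponent_only_evaluates(self):
        samples = sample_discrete_powerlaw(-1.5, 50, 5000, seed=1)
        fit = fit_power_law(samples, fixed_exponent=-1.5)
        assert fit.exponent == -1.5
        assert 0 <= fit.ks_distance <= 1

    def test_invariant_to_order_and_duplication(self):
        samples = sample_discrete_powerlaw(-2.0, 40, 2000, seed=5)
        f1 = fit_power_law(samples)
        f2 = fit_power_law(samples[::-1])
        f3 = fit_power_law(np.concatenate([samples, samples]))
        assert f1.exponent == f2.exponent == f3.exponent
        assert f1.ks_distance == f2.ks_distance == f3.ks_distance

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law(np.full(10, 7))


class TestSegmentStability:
    def test_single_segment_equals_whole_fit(self):
        _, raster = simulate_branching(BranchingSpec(20, 1.0, 500, seed=8))
        whole = fit_power_law(avalanche_sizes(raster))
        seg = segment_stability(raster, 1)
        assert seg.fits[0].exponent == pytest.approx(whole.exponent)
        assert seg.sd_exponent == 0.0

    def test_stationary_raster_is_stable(self):
        _, raster = simulate_branching(BranchingSpec(30, 1.0, 10_000, seed=9))
        seg = segment_stability(raster, 10)
        assert len(seg.fits) == 10
        assert seg.sd_exponent < 0.1 * abs(seg.mean_exponent)
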