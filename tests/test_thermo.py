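"""Temperature reweighting and thermodynamic observables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avacrit import (PatternDistribution, SizeDistribution, default_t_grid,
                     energies, fit_power_law, order_parameter, pattern_sizes,
                     perturb_quiescent, reweight, size_distribution_at_T,
                     specific_heat, susceptibility, thermo_curves)


def _two_state(p):
    return PatternDistribution([p, 1 - p], 1)


def _independent_dist(n, rate):
    """Product distribution of n independent units at a common rate."""
    sizes = pattern_sizes(n)
    probs = rate**sizes * (1 - rate) ** (n - sizes)
    return PatternDistribution(probs, n)


class TestEnergies:
    def test_uniform_two_states(self):
        spec = energies(_two_state(0.5))
        assert np.allclose(spec.energies, np.log(2))

    def test_hand_computed(self):
        spec = energies(_two_state(0.8))
        assert spec.energies == pytest.approx([0.22314, 1.60944], abs=1e-5)

    def test_zero_probability_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            spec = energies(PatternDistribution([1.0, 0.0], 1))
        assert np.isfinite(spec.energies).all()


class TestReweight:
    def test_identity_at_unit_temperature(self):
        dist = _two_state(0.8)
        out = reweight(dist, 1.0)
        assert np.allclose(out.probabilities, dist.probabilities, atol=1e-13)

    def test_hand_computed_values(self):
        assert reweight(_two_state(0.8), 2.0).probabilities == pytest.approx(
            [2 / 3, 1 / 3], abs=1e-12)
        assert reweight(_two_state(0.8), 0.5).probabilities == pytest.approx(
            [0.94117647, 0.05882353], abs=1e-8)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            reweight(_two_state(0.5), 0.0)

    @given(st.integers(0, 2**32 - 1),
           st.floats(0.3, 3.0), st.floats(0.3, 3.0))
    @settings(max_examples=40, deadline=None)
    def test_composition_and_normalization(self, seed, t1, t2):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(16))
        probs = np.clip(probs, 1e-12, None)
        dist = PatternDistribution(probs / probs.sum(), 4)
        once = reweight(reweight(dist, t1), t2)
        direct = reweight(dist, t1 * t2)
        assert abs(once.probabilities.sum() - 1) < 1e-12
        assert np.allclose(once.probabilities, direct.probabilities, atol=1e-12)


class TestObservables:
    def test_uniform_distribution_limits(self):
        n = 3
        uniform = PatternDistribution(np.full(2**n, 1 / 2**n), n)
        assert specific_heat(uniform, energies(uniform), 1.0) == pytest.approx(0.0)
        assert order_parameter(uniform) == pytest.approx(0.0)

    def test_specific_heat_hand_value(self):
        dist = PatternDistribution([0.8, 0.2], 1)
        C = specific_heat(dist, energies(dist), T=1.0, n=1)
        assert C == pytest.approx(0.30749, abs=1e-5)

    def test_quiescent_point_mass_order_parameter(self):
        dist = PatternDistribution([1.0, 0.0, 0.0, 0.0], 2)
        assert order_parameter(dist) == -1.0

    def test_order_parameter_hand_value(self):
        probs = np.zeros(4)
        probs[3] = 0.8  # both active
        probs[0] = 0.2  # quiescent
        assert order_parameter(PatternDistribution(probs, 2)) == pytest.approx(0.6)

    def test_susceptibility_point_mass_and_single_unit(self):
        point = PatternDistribution([0.0, 1.0], 1)
        assert susceptibility(point, 1.0) == 0.0
        half = PatternDistribution([0.5, 0.5], 1)
        assert susceptibility(half, 1.0) == pytest.approx(1.0)

    def test_independent_units_closed_forms(self):
        """chi = 4r(1-r) per unit regardless of n; M = 2r-1 (T = 1)."""
        for n in (2, 5, 8):
            for r in (0.2, 0.5, 0.7):
                dist = _independent_dist(n, r)
                assert susceptibility(dist, 1.0) == pytest.approx(
                    4 * r * (1 - r), abs=1e-10)
                assert order_parameter(dist) == pytest.approx(2 * r - 1, abs=1e-10)

    def test_nonnegative_observables(self, rng):
        probs = rng.dirichlet(np.ones(32))
        dist = PatternDistribution(probs, 5)
        spec = energies(dist)
        for T in (0.5, 1.0, 2.0):
            d = reweight(dist, T)
            assert specific_heat(d, spec, T) >= 0
            assert susceptibility(d, T) >= 0
            assert -1 <= order_parameter(d) <= 1


class TestCurves:
    def test_independent_family_is_size_invariant(self):
        """Independent homogeneous units: every observable identical across n."""
        r = 0.15
        T_grid = default_t_grid(0.5, 2.5, 41)
        curves = thermo_curves({n: _independent_dist(n, r) for n in (4, 6, 8)},
                               T_grid)
        by_q = {}
        for c in curves:
            by_q.setdefault(c.quantity, []).append(c.values)
        for q, vals in by_q.items():
            spread = np.ptp(np.stack(vals), axis=0)
            assert spread.max() < 1e-10, q

    def test_order_parameter_at_unit_temperature_is_mean_activity(self, rng):
        probs = rng.dirichlet(np.ones(16))
        dist = PatternDistribution(probs, 4)
        curves = thermo_curves({4: dist}, np.array([0.5, 1.0, 1.5]))
        m_curve = [c for c in curves if c.quantity == "order_parameter"][0]
        assert m_curve.values[1] == pytest.approx(order_parameter(dist), abs=1e-12)

    def test_exchangeable_specific_heat_peak_grows_with_n(self, exchangeable_ring_6):
        from avacrit import RingModelSpec, dg_pattern_distribution, ring_dg_params
        fams = {n: dg_pattern_distribution(
                    ring_dg_params(RingModelSpec(n, 0.5, float("inf"), 0.2)))
                for n in (6, 8, 10)}
        curves = thermo_curves(fams, default_t_grid(0.5, 2.5, 81))
        peaks = {c.system_size: c.values.max()
                 for c in curves if c.quantity == "specific_heat"}
        assert peaks[6] < peaks[8] < peaks[10]


class TestSizeDistributionScan:
    @staticmethod
    def _size_exchangeable_from_pmf(n, exponent, p0):
        """Pattern distribution whose size marginal is an exact power law."""
        from scipy.special import comb
        sizes = pattern_sizes(n)
        k = np.arange(1, n + 1, dtype=float)
        pmf = k**exponent / (k**exponent).sum()
        probs = np.empty(2**n)
        probs[0] = p0
        for kk in range(1, n + 1):
            probs[sizes == kk] = (1 - p0) * pmf[kk - 1] / comb(n, kk)
        return PatternDistribution(probs, n)

    def test_argmin_at_unit_temperature_for_exact_powerlaw(self):
        dist = self._size_exchangeable_from_pmf(8, -1.5, 0.3)
        scan = size_distribution_at_T(dist, np.linspace(0.8, 1.2, 41))
        assert scan.T_min_best == pytest.approx(1.0, abs=1e-9)
        assert scan.T_min_fixed == pytest.approx(1.0, abs=1e-9)
        at_T1 = scan.best_fit[20]
        assert at_T1.ks_distance < 1e-10

    def test_high_temperature_limit_is_binomial(self):
        dist = self._size_exchangeable_from_pmf(6, -1.5, 0.2)
        scan = size_distribution_at_T(dist, np.array([1.0, 500.0]))
        from scipy.stats import binom
        k = np.arange(1, 7)
        expected = binom.pmf(k, 6, 0.5)
        expected /= expected.sum()
        assert np.allclose(scan.size_distributions[-1].probabilities, expected,
                           atol=1e-2)


class TestPerturbQuiescent:
    def test_identity_and_full_renormalization(self, rng):
        probs = rng.dirichlet(np.ones(16))
        dist = PatternDistribution(probs, 4)
        same = perturb_quiescent(dist, dist.p0)
        assert np.allclose(same.probabilities, dist.probabilities, atol=1e-14)
        active_only = perturb_quiescent(dist, 0.0)
        assert active_only.p0 == 0.0
        assert np.allclose(active_only.probabilities[1:],
                           dist.probabilities[1:] / (1 - dist.p0))

    def test_size_fit_invariant_under_quiescent_change(self):
        dist = TestSizeDistributionScan._size_exchangeable_from_pmf(7, -1.8, 0.4)
        before = dist.size_marginal(include_quiescent=False)
        after_dist = perturb_quiescent(dist, 0.9)
        after = after_dist.size_marginal(include_quiescent=False)
        assert np.allclose(before, after, atol=1e-12)
        sizes = np.arange(1, 8)
        f1 = fit_power_law(SizeDistribution(sizes, before, 0))
        f2 = fit_power_law(SizeDistribution(sizes, after, 0))
        assert f1.exponent == pytest.approx(f2.exponent, abs=1e-9)
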