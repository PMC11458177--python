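"""Core signal model: closed forms, series, quadrature, ODE oracle."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import unfoldkin as uk
from unfoldkin.errors import DomainError, ParameterError, UsageError
from unfoldkin.mechanism import SchemeParams, TranslocationGeometry

RATES = st.floats(1e-3, 1.0)


class TestSchemeParams:
    @pytest.mark.parametrize("kwargs", [
        dict(k_U=0.0, k_end=0.1, n=1),
        dict(k_U=0.1, k_end=-0.1, n=1),
        dict(k_U=0.1, k_end=0.1, n=-0.5),
        dict(k_U=np.inf, k_end=0.1, n=1),
        dict(k_U=0.1, k_end=0.1, n=1, F1=-1.0),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            SchemeParams(**kwargs)


class TestStepsFromLength:
    def test_three_domain_geometry(self):
        n = uk.steps_from_length(TranslocationGeometry(362, 93, 56.5))
        assert n == pytest.approx((362 - 93) / 56.5)
        assert n == pytest.approx(4.761, abs=1e-3)

    def test_fully_pretranslocated_is_zero(self):
        assert uk.steps_from_length(TranslocationGeometry(168, 168, 56.5)) == 0

    def test_overshoot_is_domain_error(self):
        with pytest.raises(DomainError):
            uk.steps_from_length(TranslocationGeometry(168, 200, 56.5))


class TestTrivialValues:
    def test_zero_time_gives_zero_fractions(self, reference_params):
        t = np.array([0.0, 1.0])
        assert uk.last_intermediate_fraction(reference_params, t)[0] == 0.0
        assert uk.product_fraction(reference_params, t)[0] == 0.0
        assert uk.signal_values(reference_params, t)[0] == 0.0

    def test_n_zero_decays_exponentially(self, log_grid):
        p = SchemeParams(k_U=0.1, k_end=0.07, n=0)
        np.testing.assert_allclose(
            uk.last_intermediate_fraction(p, log_grid),
            np.exp(-0.07 * log_grid), rtol=1e-12)
        np.testing.assert_allclose(
            uk.product_fraction(p, log_grid),
            1 - np.exp(-0.07 * log_grid), rtol=1e-12)

    def test_product_reaches_one(self):
        p = SchemeParams(k_U=0.017, k_end=0.1, n=3)
        # past both the gamma transit (incl. its tail) and the decay tail
        t_far = np.array([(3 + 10 * np.sqrt(3)) / 0.017 + 50 / 0.1])
        assert uk.product_fraction(p, t_far)[0] == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_rates_raise(self):
        with pytest.raises(ParameterError):
            SchemeParams(k_U=-1.0, k_end=0.1, n=2)


class TestOdeOracleEquivalence:
    """The analytic evaluation must match direct integration of the chain."""

    def test_example_point_matches(self):
        p = SchemeParams(k_U=0.017, k_end=0.1, n=3)
        t = np.array([200.0])
        orc = uk.ode_oracle(p, t)
        assert uk.last_intermediate_fraction(p, t)[0] == pytest.approx(
            orc.last_intermediate[0], rel=1e-8)
        assert uk.product_fraction(p, t)[0] == pytest.approx(
            orc.product[0], rel=1e-8)

    @pytest.mark.parametrize("n", [0, 1, 2, 5, 10])
    def test_random_rate_pairs(self, n, log_grid):
        rng = np.random.default_rng(1234 + n)
        for _ in range(20):
            kU, kend = np.exp(rng.uniform(np.log(1e-3), np.log(1.0), 2))
            p = SchemeParams(kU, kend, n)
            orc = uk.ode_oracle(p, log_grid)
            last = uk.last_intermediate_fraction(p, log_grid)
            prod = uk.product_fraction(p, log_grid)
            # below ~1e-10 the chain propagator's own roundoff dominates
            m = orc.last_intermediate > 1e-10
            np.testing.assert_allclose(last[m], orc.last_intermediate[m],
                                       rtol=1e-8)
            m = orc.product > 1e-10
            np.testing.assert_allclose(prod[m], orc.product[m], rtol=1e-8)

    def test_oracle_conserves_mass(self, log_grid):
        p = SchemeParams(k_U=0.055, k_end=0.1, n=5)
        _, states = uk.ode_oracle(p, log_grid, full=True)
        np.testing.assert_allclose(states.sum(axis=0), 1.0, atol=1e-10)

    def test_one_step_two_exponential_solution(self, log_grid):
        kU, kend = 0.02, 0.007
        p = SchemeParams(kU, kend, n=1)
        orc = uk.ode_oracle(p, log_grid)
        expected = kU / (kend - kU) * (np.exp(-kU * log_grid)
                                       - np.exp(-kend * log_grid))
        np.testing.assert_allclose(orc.last_intermediate, expected,
                                   rtol=1e-9, atol=1e-12)

    def test_non_integer_n_rejected(self, log_grid):
        with pytest.raises(UsageError):
            uk.ode_oracle(SchemeParams(0.1, 0.1, 2.5), log_grid)


class TestBackendEquivalence:
    """Closed form / series and the independent quadrature backend must
    agree, including at non-integer n."""

    @pytest.mark.parametrize("kU,kend,n", [
        (0.055, 0.01, 4.76), (0.1, 0.02, 2.5), (0.2, 0.01, 0.7),
        (0.017, 0.05, 1.327), (0.017, 0.03, 3.04), (0.0042, 0.008, 3.73),
        (0.1, 0.1, 2.5), (1e-3, 1.0, 1.5),
    ])
    def test_auto_vs_quadrature(self, kU, kend, n, log_grid):
        p = SchemeParams(kU, kend, n)
        for func in (uk.last_intermediate_fraction, uk.product_fraction):
            a = func(p, log_grid)
            q = func(p, log_grid, backend="quad")
            m = q > 1e-12
            np.testing.assert_allclose(a[m], q[m], rtol=1e-7)

    def test_against_high_precision_talbot(self):
        p = SchemeParams(0.017, 0.1, 4.76)
        t = np.array([10.0, 100.0, 300.0, 1000.0])
        last_ref, prod_ref = uk.talbot_reference(p, t)
        np.testing.assert_allclose(uk.last_intermediate_fraction(p, t),
                                   last_ref, rtol=1e-9)
        np.testing.assert_allclose(uk.product_fraction(p, t), prod_ref,
                                   rtol=1e-9)

    def test_equal_rates_handled_natively(self, log_grid):
        p = SchemeParams(0.05, 0.05, 3.5)
        a = uk.last_intermediate_fraction(p, log_grid)
        q = uk.last_intermediate_fraction(p, log_grid, backend="quad")
        m = q > 1e-12
        np.testing.assert_allclose(a[m], q[m], rtol=1e-7)


class TestConservationProperties:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(kU=RATES, kend=RATES, n=st.floats(0.0, 20.0))
    def test_fractions_bounded_and_monotone(self, kU, kend, n):
        p = SchemeParams(kU, kend, n)
        t = np.geomspace(1e-2, 2000.0, 40)
        sp = uk.species_fractions(p, t)
        assert np.all(sp.last_intermediate >= -1e-12)
        assert np.all(sp.product >= -1e-12)
        assert np.all(sp.last_intermediate + sp.product <= 1 + 1e-8)
        assert np.all(np.diff(sp.product) >= -1e-8)


class TestSignal:
    def test_equal_amplitudes_monotone(self, log_grid):
        p = SchemeParams(0.017, 0.05, 3.0, F1=0.8, F2=0.8)
        y = uk.signal_values(p, log_grid)
        assert np.all(np.diff(y) >= -1e-12)
        assert y[-1] == pytest.approx(0.8, rel=1e-3)

    def test_single_interior_maximum(self):
        p = SchemeParams(0.017, 0.012, (362 - 93) / 56.5, F1=1.0, F2=0.05)
        t = np.geomspace(1.0, 5000.0, 5000)
        y = uk.signal_values(p, t)
        i = np.argmax(y)
        assert 0 < i < len(t) - 1
        # one sign change of the derivative (ignoring flat-region jitter
        # at the evaluation-precision floor)
        dy = np.diff(y)
        s = np.sign(dy[np.abs(dy) > 1e-11 * np.max(y)])
        sign_changes = np.sum(np.diff(s) != 0)
        assert sign_changes == 1

    def test_signal_timecourse_wraps_timecourse(self, reference_params, log_grid):
        tc = uk.signal_timecourse(reference_params, log_grid, substrate="RepA-Titin_3",
                           length=362.0)
        assert tc.state == "relative"
        assert tc.substrate == "RepA-Titin_3"
        np.testing.assert_array_equal(
            tc.y, uk.signal_values(reference_params, log_grid))


class TestPeakTime:
    def test_matches_dense_grid_argmax_sharp_peak(self):
        p = SchemeParams(0.017, 0.012, 4.76, F1=1.0, F2=0.05)
        pk = uk.peak_time_of_signal(p)
        assert pk.has_peak
        grid = np.geomspace(10.0, 5000.0, 100_000)
        brute = grid[np.argmax(uk.signal_values(p, grid))]
        assert pk.time == pytest.approx(brute, abs=0.5)

    def test_matches_dense_grid_argmax_flat_peak(self):
        # here the interior maximum exceeds the F2 asymptote by only ~1e-11,
        # so the peak *location* is ill-conditioned; the detected peak must
        # still sit on the brute-force plateau at the maximal value
        p = SchemeParams(0.0042, 0.02, 2.0, F1=1.0, F2=0.2)
        pk = uk.peak_time_of_signal(p)
        assert pk.has_peak
        grid = np.geomspace(1.0, 3e4, 100_000)
        y = uk.signal_values(p, grid)
        assert pk.value == pytest.approx(np.max(y), abs=1e-11)
        assert abs(pk.time - grid[np.argmax(y)]) < 300.0

    def test_strictly_increasing_with_n(self):
        times = [uk.peak_time_of_signal(
            SchemeParams(0.017, 0.012, n, F1=1.0, F2=0.05)).time
            for n in range(1, 11)]
        assert np.all(np.diff(times) > 0)

    def test_no_peak_when_F1_below_F2(self):
        pk = uk.peak_time_of_signal(SchemeParams(0.017, 0.05, 3, F1=0.2,
                                                 F2=1.0))
        assert not pk.has_peak
        assert np.isnan(pk.time)

    def test_peak_value_matches_brute_force(self, reference_params):
        pk = uk.peak_time_of_signal(reference_params)
        grid = np.geomspace(pk.time * 0.5, pk.time * 2, 100_000)
        brute = np.max(uk.signal_values(reference_params, grid))
        assert pk.value == pytest.approx(brute, rel=1e-6)


class TestLengthPeakTimeConsistency:
    def test_implied_rate_close_to_m_kU(self):
        """Peak times across the three lengths imply a length-vs-time slope
        within 15% of m*k_U (documented finite-n bias)."""
        m, kU, C = 56.5, 0.017, 93.0
        lengths = np.array([168.0, 265.0, 362.0])
        kends = (0.012, 0.011, 0.010)
        times = [uk.peak_time_of_signal(
            SchemeParams(kU, ke, (L - C) / m, F1=1.0, F2=0.05)).time
            for L, ke in zip(lengths, kends)]
        slope = np.polyfit(times, lengths, 1)[0]
        assert slope == pytest.approx(m * kU, rel=0.15)
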