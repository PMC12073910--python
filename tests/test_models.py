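"""Forward-model values, limits and cross-oracle consistency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metabdiff.models import (
    AstroSticksParams,
    KurtosisParams,
    KurtosisValidityWarning,
    ModAstroSticksParams,
    MonoexpParams,
    analytic_moments_astrosticks,
    astrosticks_signal,
    highb_loglog_slope,
    kurtosis_signal,
    mod_astrosticks_signal,
    mod_astrosticks_valid,
    monoexp_signal,
    powder_average_mc,
)


class TestMonoexp:
    @pytest.mark.parametrize(
        "b, adc, expected",
        [
            (0.0, 0.105, 1.0),
            # exp(-1.012 * 0.105), checked against mpmath-style evaluation
            (1.012, 0.105, 0.8991908280653429),
            (4.03, 1e-12, 1.0),
        ],
    )
    def test_values(self, b, adc, expected):
        assert monoexp_signal(b, MonoexpParams(adc)) == pytest.approx(
            expected, abs=1e-9)

    def test_negative_b_rejected(self):
        with pytest.raises(ValueError):
            monoexp_signal(-1.0, MonoexpParams(0.2))

    def test_strictly_decreasing(self, b_values):
        s = monoexp_signal(b_values, MonoexpParams(0.3))
        assert np.all(np.diff(s) < 0)


class TestKurtosis:
    def test_table_value(self):
        # exponent -9.06*0.126 + (9.06*0.126)^2 * 2.108 / 6 by hand
        expo = -9.06 * 0.126 + (9.06 * 0.126) ** 2 * 2.108 / 6.0
        expected = np.exp(expo)
        assert expected == pytest.approx(0.50474, abs=5e-5)
        assert kurtosis_signal(9.06, KurtosisParams(0.126, 2.108)) == \
            pytest.approx(expected, rel=1e-12)

    def test_zero_b_identity(self):
        assert kurtosis_signal(0.0, KurtosisParams(0.5, 2.0)) == 1.0

    def test_k_zero_reduces_to_monoexp(self):
        assert kurtosis_signal(5.0, KurtosisParams(0.2, 0.0)) == \
            pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_warns_beyond_turnover(self):
        p = KurtosisParams(0.5, 2.0)  # b* = 3
        with pytest.warns(KurtosisValidityWarning):
            kurtosis_signal(4.0, p)

    def test_no_warning_below_turnover(self, recwarn):
        kurtosis_signal(2.0, KurtosisParams(0.5, 2.0))
        assert not any(isinstance(w.message, KurtosisValidityWarning)
                       for w in recwarn.list)


class TestAstroSticks:
    def test_closed_form_value(self):
        # sqrt(pi)/2 * erf(sqrt(x))/sqrt(x) at x = 25.1 * 0.346
        assert astrosticks_signal(25.1, AstroSticksParams(0.346)) == \
            pytest.approx(0.3007160886164984, abs=1e-12)

    def test_small_argument_series(self):
        # x = 0.01 * 0.346 = 3.46e-3: closed form still fine, matches series
        x = 0.01 * 0.346
        series = 1 - x / 3 + x**2 / 10 - x**3 / 42
        assert astrosticks_signal(0.01, AstroSticksParams(0.346)) == \
            pytest.approx(series, abs=1e-9)
        # far below the series switchover the value must stay finite and ~1
        assert astrosticks_signal(1e-9, AstroSticksParams(0.346)) == \
            pytest.approx(1.0, abs=1e-9)

    def test_zero_b_identity(self):
        assert astrosticks_signal(0.0, AstroSticksParams(0.346)) == 1.0

    def test_monte_carlo_cross_check(self):
        mean, se = powder_average_mc(25.1, 0.346, 0.0, 400_000, seed=20)
        closed = astrosticks_signal(25.1, AstroSticksParams(0.346))
        assert abs(closed - mean) < 3 * se

    @given(st.floats(0.05, 1.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_decreasing_in_dintra(self, d):
        s1 = astrosticks_signal(9.06, AstroSticksParams(d))
        s2 = astrosticks_signal(9.06, AstroSticksParams(min(d + 0.01, 1.0)))
        assert 0 < s2 <= s1 <= 1


class TestModAstroSticks:
    def test_kintra_zero_reduction(self, b_values):
        p = ModAstroSticksParams(0.384, 0.0)
        q = AstroSticksParams(0.384)
        diff = np.abs(mod_astrosticks_signal(b_values, p)
                      - astrosticks_signal(b_values, q))
        assert diff.max() < 1e-8

    def test_kintra_zero_reduction_random_dintra(self, b_values):
        rng = np.random.default_rng(11)
        for d in rng.uniform(0.05, 1.0, 100):
            diff = np.abs(
                mod_astrosticks_signal(b_values, ModAstroSticksParams(d, 0.0))
                - astrosticks_signal(b_values, AstroSticksParams(d)))
            assert diff.max() < 1e-8

    def test_monte_carlo_cross_check(self):
        p = ModAstroSticksParams(0.384, 0.071)
        mean, se = powder_average_mc(25.1, 0.384, 0.071, 400_000, seed=21)
        assert abs(mod_astrosticks_signal(25.1, p) - mean) < 3 * se

    def test_zero_b_identity(self):
        assert mod_astrosticks_signal(0.0, ModAstroSticksParams(0.5, 1.0)) \
            == pytest.approx(1.0, abs=1e-12)

    def test_quadrature_converged(self, b_values):
        # doubling the order must not move any value beyond 1e-8 anywhere
        # the effective diffusivity stays non-negative (Kintra*Dintra*b <= 1)
        for d, k in [(0.05, 0.5), (0.3, 0.13), (0.9, 0.04), (0.346, 0.0),
                     (1.0, 0.0398)]:
            assert mod_astrosticks_valid(25.1, ModAstroSticksParams(d, k))
            mod_astrosticks_signal(b_values, ModAstroSticksParams(d, k),
                                   check_convergence=True)

    def test_validity_flag(self):
        # Kintra*Dintra*b > 1 drives Deff negative at cos(theta)=1
        assert not mod_astrosticks_valid(25.1, ModAstroSticksParams(0.5, 1.0))
        assert mod_astrosticks_valid(25.1, ModAstroSticksParams(0.384, 0.071))


class TestPowderAverageMC:
    def test_zero_b(self):
        mean, se = powder_average_mc(0.0, 0.4, 0.1, 10_000, seed=1)
        assert mean == 1.0 and se == 0.0

    def test_reproducible(self):
        a = powder_average_mc(9.06, 0.44, 0.0, 50_000, seed=7)
        b = powder_average_mc(9.06, 0.44, 0.0, 50_000, seed=7)
        assert a == b

    def test_rejects_tiny_sample(self):
        with pytest.raises(ValueError):
            powder_average_mc(1.0, 0.4, 0.0, 100, seed=1)

    def test_three_way_agreement(self):
        """Closed form, quadrature and Monte Carlo agree on a (b, D) grid."""
        rng_seed = 33
        for b in (1.012, 9.06, 25.1):
            for d in (0.1, 0.346, 0.9):
                closed = astrosticks_signal(b, AstroSticksParams(d))
                quad = mod_astrosticks_signal(b, ModAstroSticksParams(d, 0.0))
                assert closed == pytest.approx(quad, abs=1e-8)
                mc, se = powder_average_mc(b, d, 0.0, 200_000, seed=rng_seed)
                assert abs(closed - mc) < 3 * se


class TestAnalyticLimits:
    @pytest.mark.parametrize("d", [0.3, 0.9])
    def test_moments(self, d):
        adc, k = analytic_moments_astrosticks(AstroSticksParams(d))
        assert adc == pytest.approx(d / 3.0, rel=1e-14)
        assert k == pytest.approx(2.4, rel=1e-14)

    def test_highb_slope_sticks(self):
        s = highb_loglog_slope(AstroSticksParams(0.4), (16.09, 25.1))
        assert s == pytest.approx(-0.5, abs=0.01)

    def test_highb_slope_sticks_dintra_range(self):
        """Stick scaling reaches -1/2 once b*Dintra is truly asymptotic.

        Below Dintra ~ 0.25 the lower protocol b-value (16.09) gives
        b*Dintra ~ 3-4 and the exact slope still sits a few hundredths
        above -1/2; the approach is monotone in Dintra.
        """
        slopes = [highb_loglog_slope(AstroSticksParams(d), (16.09, 25.1))
                  for d in np.linspace(0.2, 0.5, 13)]
        for d, s in zip(np.linspace(0.2, 0.5, 13), slopes):
            if d >= 0.25:
                assert abs(s + 0.5) < 0.01
            else:
                assert -0.5 < s < -0.45
        assert np.all(np.diff(slopes) < 0)  # monotone approach to -1/2

    def test_highb_slope_asymptotic_limit(self):
        s = highb_loglog_slope(AstroSticksParams(0.3), (1e4, 2e4))
        assert s == pytest.approx(-0.5, abs=1e-4)

    def test_gaussian_decay_violates_stick_signature(self):
        s = highb_loglog_slope(MonoexpParams(0.4), (16.09, 25.1))
        assert s < -1.0

    def test_equal_b_rejected(self):
        with pytest.raises(ValueError):
            highb_loglog_slope(AstroSticksParams(0.4), (9.06, 9.06))


class TestParameterValidation:
    @pytest.mark.parametrize("ctor, kwargs", [
        (MonoexpParams, {"ADC": 0.0}),
        (MonoexpParams, {"ADC": 1.2}),
        (KurtosisParams, {"ADC": 0.3, "K": 3.5}),
        (KurtosisParams, {"ADC": 0.3, "K": -0.1}),
        (AstroSticksParams, {"Dintra": -0.2}),
        (ModAstroSticksParams, {"Dintra": 0.4, "Kintra": 4.0}),
    ])
    def test_out_of_box_rejected(self, ctor, kwargs):
        with pytest.raises(ValueError):
            ctor(**kwargs)

    def test_signals_bounded_on_protocol(self, b_values):
        """S(0)=1 and 0 < S <= 1 across the protocol for all models."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            d = rng.uniform(0.05, 1.0)
            k = rng.uniform(0.0, 3.0)
            for s in (monoexp_signal(b_values, MonoexpParams(d)),
                      astrosticks_signal(b_values, AstroSticksParams(d)),
                      mod_astrosticks_signal(
                          b_values[b_values * d * max(k, 1e-9) <= 1.0],
                          ModAstroSticksParams(d, k))):
                assert np.all(s > 0) and np.all(s <= 1.0)
            p = KurtosisParams(d, k)
            bb = b_values[b_values < p.b_turnover]
            if bb.size:
                s = kurtosis_signal(bb, p)
                assert np.all(s > 0) and np.all(s <= 1.0)
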