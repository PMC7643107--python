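import pytest
from hypothesis import given, strategies as st

from spiralsort import (
    DensityCoefficientModel,
    RectChannel,
    ThresholdModel,
    calibrate_density_model,
    characteristic_length,
    coefficient_from_threshold,
    density_coefficient,
    hydraulic_diameter,
    is_focused,
    reference_device,
    round_to_half_micron,
    round_to_micron,
    threshold_diameter,
    tm3_rounded_chain,
)
from spiralsort.errors import CalibrationError, DomainError


class TestCharacteristicLength:
    def test_tm1_is_hydraulic_diameter(self, channel):
        assert characteristic_length("TM1", channel) == hydraulic_diameter(channel)

    def test_tm2_is_height(self, channel):
        assert characteristic_length("TM2", channel) == channel.height

    def test_tm3_blend(self, channel):
        # (305.5556 + 3*220)/4 um
        assert characteristic_length("TM3", channel) * 1e6 == pytest.approx(241.39, abs=0.01)

    def test_unknown_model_rejected(self, channel):
        with pytest.raises(ValueError):
            characteristic_length("TM9", channel)


class TestThresholdDiameter:
    def test_tm1_rounds_to_21_um(self, channel):
        t = threshold_diameter("TM1", channel)
        assert t * 1e6 == pytest.approx(21.39, abs=0.01)
        assert round_to_micron(t) * 1e6 == pytest.approx(21)

    def test_tm2_rounds_to_15_um(self, channel):
        t = threshold_diameter("TM2", channel)
        assert t * 1e6 == pytest.approx(15.4, abs=0.01)
        assert round_to_micron(t) * 1e6 == pytest.approx(15)

    def test_tm4_talc_rounds_to_26_um(self, channel):
        c = density_coefficient(2.75)
        t = threshold_diameter("TM4", channel, c)
        assert round_to_micron(t) * 1e6 == pytest.approx(26)

    def test_tm4_equals_tm1_at_unit_coefficient(self, channel):
        assert threshold_diameter("TM4", channel, 1.0) == threshold_diameter("TM1", channel)

    def test_tm4_rejects_sub_unit_coefficient(self, channel):
        with pytest.raises(DomainError):
            threshold_diameter("TM4", channel, 0.9)

    def test_tm3_formula_vs_rounded_chain(self, channel):
        # full-precision formula: 0.07*(D+3h)/4 = 16.90 um; rounded-chain
        # display convention: (21 + 3*15)/4 = 16.5 um
        assert threshold_diameter("TM3", channel) * 1e6 == pytest.approx(16.897, abs=1e-3)
        assert tm3_rounded_chain(channel) * 1e6 == pytest.approx(16.5, abs=1e-9)

    @given(
        w=st.floats(min_value=2e-6, max_value=2e-3),
        h=st.floats(min_value=1e-6, max_value=2e-3),
    )
    def test_ordering_tm2_tm3_tm1_for_wide_channels(self, w, h):
        if w <= h:
            w, h = 2 * h, w  # force aspect ratio w > h
        ch = RectChannel(width=w, height=h)
        t1 = threshold_diameter("TM1", ch)
        t2 = threshold_diameter("TM2", ch)
        t3 = threshold_diameter("TM3", ch)
        assert t2 <= t3 * (1 + 1e-12)
        assert t3 <= t1 * (1 + 1e-12)

    @given(rho=st.lists(st.floats(min_value=1.05, max_value=2.75), min_size=2, max_size=8))
    def test_tm4_monotone_in_density(self, rho):
        ch = reference_device()
        ts = [threshold_diameter("TM4", ch, density_coefficient(r)) for r in sorted(rho)]
        assert all(b >= a for a, b in zip(ts, ts[1:]))


class TestDensityCoefficient:
    def test_pet(self):
        assert density_coefficient(1.38) == pytest.approx(1.04226, rel=1e-9)
        assert round(density_coefficient(1.38), 2) == 1.04

    def test_pa(self):
        assert density_coefficient(1.15) == pytest.approx(1.01305, rel=1e-9)
        assert round(density_coefficient(1.15), 3) == 1.013

    def test_low_density_near_clamp(self):
        # raw line value 1.00035 stays just above the clamp
        assert density_coefficient(1.05) == pytest.approx(1.00035, rel=1e-9)

    def test_clamped_below_unity(self):
        with pytest.warns(UserWarning, match="outside the calibrated range"):
            assert density_coefficient(1.0) == 1.0

    def test_nonpositive_density_rejected(self):
        with pytest.raises(DomainError):
            density_coefficient(0.0)

    def test_out_of_range_warns_not_fails(self):
        with pytest.warns(UserWarning):
            c = density_coefficient(3.5)
        assert c > 1.0


class TestCalibration:
    def test_published_coefficients_from_two_anchors(self, channel):
        c_talc = coefficient_from_threshold(26e-6, channel)
        model = calibrate_density_model([(1.05, 1.0), (2.75, c_talc)])
        assert round(model.slope, 3) == 0.127
        assert round(model.intercept, 3) == 0.867
        assert model.valid_range == (1.05, 2.75)

    def test_flat_line(self):
        model = calibrate_density_model([(1.0, 1.0), (2.0, 1.0)])
        assert model.slope == pytest.approx(0.0, abs=1e-12)
        assert model.intercept == pytest.approx(1.0, rel=1e-12)

    def test_collinear_anchors_agree_with_pairwise_fit(self):
        pts = [(1.0, 1.0), (2.0, 1.2), (3.0, 1.4)]
        m3 = calibrate_density_model(pts)
        m2 = calibrate_density_model(pts[:2])
        assert m3.slope == pytest.approx(m2.slope, rel=1e-9)
        assert m3.intercept == pytest.approx(m2.intercept, rel=1e-9)

    def test_rejects_degenerate_input(self):
        with pytest.raises(CalibrationError):
            calibrate_density_model([(1.0, 1.0)])
        with pytest.raises(CalibrationError):
            calibrate_density_model([(1.0, 1.0), (1.0, 1.2)])

    @given(
        rho1=st.floats(min_value=1.0, max_value=1.9),
        rho2=st.floats(min_value=2.0, max_value=3.0),
        c1=st.floats(min_value=1.0, max_value=1.1),
        c2=st.floats(min_value=1.1, max_value=1.5),
    )
    def test_two_anchor_fit_interpolates_exactly(self, rho1, rho2, c1, c2):
        model = calibrate_density_model([(rho1, c1), (rho2, c2)])
        assert model.slope * rho1 + model.intercept == pytest.approx(c1, abs=1e-12)
        assert model.slope * rho2 + model.intercept == pytest.approx(c2, abs=1e-12)


class TestCoefficientFromThreshold:
    def test_baseline(self, channel):
        t1 = threshold_diameter("TM1", channel)
        assert coefficient_from_threshold(t1, channel) == pytest.approx(1.0, rel=1e-12)

    def test_talc_inversion(self, channel):
        # 26 um / 21.389 um
        assert coefficient_from_threshold(26e-6, channel) == pytest.approx(1.2156, abs=1e-4)

    @given(c=st.floats(min_value=1.0, max_value=2.0))
    def test_inverse_of_tm4(self, c):
        ch = reference_device()
        t = threshold_diameter("TM4", ch, c)
        assert coefficient_from_threshold(t, ch) == pytest.approx(c, rel=1e-12)


class TestIsFocused:
    def test_just_below_and_above_tm1(self, channel):
        assert not is_focused(21e-6, "TM1", channel)
        assert is_focused(21.5e-6, "TM1", channel)

    def test_far_above_threshold(self, channel):
        assert is_focused(1e-3, "TM1", channel)

    def test_marginal_talc(self, channel):
        # the 26-um threshold comparison succeeds at reporting granularity
        assert is_focused(26e-6, "TM4", channel, density_g_per_ml=2.75)
        # but not under a strict comparison (threshold is 26.014 um)
        assert not is_focused(26e-6, "TM4", channel, density_g_per_ml=2.75, atol=0.0)

    def test_tm4_needs_density(self, channel):
        with pytest.raises(DomainError):
            is_focused(26e-6, "TM4", channel)


def test_rounding_helpers():
    assert round_to_micron(21.389e-6) == pytest.approx(21e-6, rel=1e-12)
    assert round_to_half_micron(21.6e-6) == pytest.approx(21.5e-6, rel=1e-12)
    assert round_to_half_micron(22.3e-6) == pytest.approx(22.5e-6, rel=1e-12)


def test_half_micron_thresholds_for_intermediate_densities(channel):
    """TM4 display thresholds at half-micron granularity for PA and PET."""
    d = hydraulic_diameter(channel)
    t_pa = threshold_diameter("TM4", channel, density_coefficient(1.15))
    t_pet = threshold_diameter("TM4", channel, density_coefficient(1.38))
    assert round_to_half_micron(t_pa) * 1e6 == pytest.approx(21.5)
    assert round_to_half_micron(t_pet) * 1e6 == pytest.approx(22.5)
    assert d * 1e6 == pytest.approx(305.56, abs=0.01)


def test_default_model_c_at_least_one_over_valid_range():
    model = DensityCoefficientModel()
    lo, hi = model.valid_range
    for rho in (lo, (lo + hi) / 2, hi):
        assert model.predict(rho) >= 1.0
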