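"""Figure-of-merit calculus: worked values, identities and scaling laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fastflim import merit
from fastflim.decay import ParameterError
from fastflim.merit import InstrumentSpec, PrecisionSpec, SampleSpec


class TestPileupLoss:
    def test_zero_rate_has_no_loss(self):
        assert merit.pileup_loss(0.0, 1e-7) == 0.0

    def test_unit_rate_deadtime_product_loses_half(self):
        assert merit.pileup_loss(1e6, 1e-6) == pytest.approx(0.5)

    def test_800khz_at_100ns(self):
        # k0*td = 0.08 -> 0.08/1.08
        assert merit.pileup_loss(0.8e6, 100e-9) == pytest.approx(0.08 / 1.08)

    @given(k0=st.floats(1e3, 1e9), td=st.floats(1e-10, 1e-6))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_monotone(self, k0, td):
        d = merit.pileup_loss(k0, td)
        assert 0.0 <= d < 1.0
        assert merit.pileup_loss(k0 * 1.5, td) > d
        assert merit.pileup_loss(k0, td * 1.5) > d

    def test_rate_for_loss_inverts(self):
        k0 = merit.rate_for_loss(0.05, 2.5e-9)
        assert merit.pileup_loss(k0, 2.5e-9) == pytest.approx(0.05, rel=1e-12)


class TestExposureAndThroughput:
    def test_shot_noise_limited_exposure(self):
        spec = PrecisionSpec(F=1.0, snr0=100.0)
        inst = InstrumentSpec(td=0.0, k0=1e6)
        assert merit.required_exposure(spec, inst) == pytest.approx(1e-2)

    def test_unit_pileup_product_doubles_exposure(self):
        spec = PrecisionSpec(F=1.3, snr0=50.0)
        base = merit.required_exposure(spec, InstrumentSpec(td=0.0, k0=1e6))
        doubled = merit.required_exposure(spec, InstrumentSpec(td=1e-6, k0=1e6))
        assert doubled == pytest.approx(2 * base)

    def test_exposure_quadratic_in_F(self):
        inst = InstrumentSpec(td=5e-9, k0=1e6)
        e1 = merit.required_exposure(PrecisionSpec(F=1.0, snr0=30.0), inst)
        e2 = merit.required_exposure(PrecisionSpec(F=2.0, snr0=30.0), inst)
        assert e2 == pytest.approx(4 * e1)

    def test_zero_rate_is_an_error(self):
        with pytest.raises(ParameterError):
            merit.required_exposure(PrecisionSpec(), InstrumentSpec(td=0.0, k0=0.0))

    def test_zero_deadtime_throughput_is_rate_over_saturation(self):
        spec = PrecisionSpec(F=1.0, snr0=10.0)
        sample = SampleSpec(n=2.0, tau=3e-9)
        inst = InstrumentSpec(td=0.0, k0=1e6)
        assert merit.throughput(spec, inst, sample) == pytest.approx(3e-9 * 1e6 / 2.0)

    @given(
        k0=st.floats(1e4, 1e8),
        td=st.floats(1e-10, 1e-6),
        F=st.floats(1.0, 3.0),
        n=st.floats(0.5, 100.0),
        tau=st.floats(5e-10, 1e-8),
    )
    @settings(max_examples=100, deadline=None)
    def test_rate_form_equals_loss_form(self, k0, td, F, n, tau):
        """The two throughput expressions are the same algebraic object."""
        spec = PrecisionSpec(F=F, snr0=20.0)
        sample = SampleSpec(n=n, tau=tau)
        a_rate = merit.throughput(spec, InstrumentSpec(td=td, k0=k0), sample)
        a_loss = merit.throughput_from_loss(spec, sample, merit.pileup_loss(k0, td), td)
        assert a_rate == pytest.approx(a_loss, rel=1e-12)
        # dead-time-imposed ceiling
        assert a_rate <= (tau / n) / F**2 / td * (1 + 1e-12)


class TestFrameRate:
    def test_quadratic_pixel_scaling(self):
        spec = PrecisionSpec(F=1.0, snr0=31.6)
        fr256 = merit.frame_rate(256, spec, 0.05, 2.5e-9)
        fr512 = merit.frame_rate(512, spec, 0.05, 2.5e-9)
        assert fr512 == pytest.approx(fr256 / 4)

    def test_defining_identity(self):
        spec = PrecisionSpec(F=1.2, snr0=31.6)
        fr = merit.frame_rate(256, spec, 0.05, 2.5e-9)
        assert fr * 256**2 * spec.required_photons * 2.5e-9 / 0.05 == pytest.approx(1.0)

    def test_consistent_with_exposure_path(self):
        spec = PrecisionSpec(F=1.0, snr0=31.6)
        delta, td = 0.05, 2.5e-9
        k0 = merit.rate_for_loss(delta, td)
        per_pixel = merit.required_exposure(spec, InstrumentSpec(td=td, k0=k0))
        assert merit.frame_rate(256, spec, delta, td) == pytest.approx(
            1.0 / (256**2 * per_pixel)
        )


class TestDynamicRange:
    """Hybrid-PMT and SPAD worked examples of the dB calculus."""

    def test_reference_term_hybrid_pmt(self):
        assert merit.dynamic_range_ref(0.05, 600.0) == pytest.approx(-53.80, abs=0.01)

    @pytest.mark.parametrize(
        "td, expected",
        [(100e-9, 86.20), (10e-9, 106.20), (1e-9, 126.20)],
    )
    def test_hybrid_pmt_vs_deadtime(self, td, expected):
        assert merit.dynamic_range(0.05, 600.0, td) == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize("td, expected", [(100e-9, 90.97), (10e-9, 110.97)])
    def test_spad_example(self, td, expected):
        assert merit.dynamic_range(0.05, 200.0, td) == pytest.approx(expected, abs=0.01)

    def test_direct_rate_form_agrees(self):
        # k_detected = delta/td is the loss-implied detected rate
        assert merit.dynamic_range(0.05, 600.0, 1e-8) == pytest.approx(
            merit.dynamic_range_from_rate(0.05 / 1e-8, 600.0)
        )

    def test_unit_ratio_is_zero_db(self):
        assert merit.dynamic_range_ref(1.0, 1.0) == pytest.approx(0.0)

    def test_monotone_decreasing_in_deadtime(self):
        tds = np.logspace(-10, -6, 20)
        values = [merit.dynamic_range(0.05, 600.0, td) for td in tds]
        assert np.all(np.diff(values) < 0)

    def test_db_scaling_law(self):
        d1 = merit.dynamic_range_ref(0.01, 400.0)
        d10 = merit.dynamic_range_ref(0.1, 400.0)
        assert d10 - d1 == pytest.approx(20.0)

    def test_zero_dcr_rejected(self):
        with pytest.raises(ParameterError):
            merit.dynamic_range_ref(0.05, 0.0)


class TestResolutionAndBlur:
    def test_green_high_na_resolution(self):
        assert merit.diffraction_resolution(500.0, 1.2) == pytest.approx(250.0)

    def test_linear_in_wavelength_and_unit_identity(self):
        assert merit.diffraction_resolution(1000.0, 1.2) == pytest.approx(500.0)
        assert merit.diffraction_resolution(1.0, 0.6) == pytest.approx(1.0)

    def test_brownian_displacement(self):
        assert merit.brownian_displacement(1e5, 0.0) == 0.0
        assert merit.brownian_displacement(1e5, 4.0) == pytest.approx(
            2 * merit.brownian_displacement(1e5, 1.0)
        )
        # one-minute exposure of an organelle-scale diffuser
        assert merit.brownian_displacement(1e5, 60.0) == pytest.approx(3464.1, abs=0.1)
        assert merit.brownian_displacement(1e5, 60.0, factor_two=False) == pytest.approx(
            2449.5, abs=0.1
        )

    def test_blur_examples(self):
        assert merit.blur_figure(250.0, 250.0) == 0.0
        assert merit.blur_figure(250.0, 800.0) == pytest.approx(-10.10, abs=0.01)
        assert merit.blur_figure(250.0, 100.0) == 0.0  # capped: immobility is not a gain

    def test_blur_db_scaling(self):
        assert merit.blur_figure(250.0, 8000.0) - merit.blur_figure(250.0, 800.0) == pytest.approx(
            -20.0
        )

    def test_parametric_blur_equals_compositional_pipeline(self):
        """B_ref - 10*log10(td) must equal exposure -> displacement -> dB."""
        rng = np.random.default_rng(1234)
        for _ in range(1000):
            spec = PrecisionSpec(F=rng.uniform(1, 3), snr0=rng.uniform(5, 200))
            delta = rng.uniform(0.005, 0.6)
            d_diff = 10.0 ** rng.uniform(2, 7)
            td = 10.0 ** rng.uniform(-9.5, -6.5)
            R = rng.uniform(100, 600)
            k0 = merit.rate_for_loss(delta, td)
            exposure = merit.required_exposure(spec, InstrumentSpec(td=td, k0=k0))
            direct = merit.blur_figure(R, merit.brownian_displacement(d_diff, exposure))
            parametric = merit.blur_from_params(R, spec, delta, d_diff, td)
            assert parametric == pytest.approx(direct, abs=1e-9)


class TestInstrumentHelpers:
    def test_safe_count_rate(self):
        assert merit.safe_count_rate(80e6) == pytest.approx(800e3)
        assert merit.safe_count_rate(80e6, divisor=10) == pytest.approx(8e6)

    def test_multi_hit_capacity(self):
        assert merit.multi_hit_capacity(32, 10) == pytest.approx(3.2)

    def test_burst_rate_from_pulse_pair_resolution(self):
        assert merit.burst_rate(5.5e-9) == pytest.approx(181.8e6, rel=1e-3)
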