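"""Dye calibration, buffering capacity, flux and permeability inference."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxsort import ph_core
from fluxsort.ph_core import (
    BufferSpec,
    CalibrationCurve,
    DegenerateGradientError,
    InsufficientDataError,
    LactateContext,
    OutOfRangeError,
    PhTimecourse,
    ProtocolError,
    ZeroBufferingError,
    buffering_capacity,
    chc_shift,
    estimate_rate,
    fermentative_flux,
    hlac_concentration,
    permeability_from_washout,
    ph_to_ratio,
    ratio_to_ph,
)


class TestCalibration:
    @pytest.mark.parametrize(
        "ratio, expected",
        [
            (1.0, 7.5),                                  # midpoint -> pKa
            (0.7, 7.5 + math.log10(0.9 / 0.3)),          # closed form
        ],
    )
    def test_known_points(self, cal, ratio, expected):
        assert ratio_to_ph(ratio, cal) == pytest.approx(expected, abs=1e-9)

    def test_direction_flips_sign(self):
        dec = CalibrationCurve(0.4, 1.6, 7.5, "decreasing")
        inc = CalibrationCurve(0.4, 1.6, 7.5, "increasing")
        # below-midpoint ratio: acid side for increasing, alkaline for decreasing
        assert ratio_to_ph(0.7, dec) > 7.5 > ratio_to_ph(0.7, inc)

    @given(st.floats(min_value=0.401, max_value=1.599))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, ratio):
        cal = CalibrationCurve(0.4, 1.6, 7.5)
        assert ph_to_ratio(ratio_to_ph(ratio, cal), cal) == pytest.approx(
            ratio, abs=1e-9
        )

    def test_out_of_range_names_sample(self, cal):
        with pytest.raises(OutOfRangeError, match="cell7"):
            ratio_to_ph(1.7, cal, label="cell7")
        with pytest.raises(OutOfRangeError):
            ratio_to_ph(0.4, cal)  # closed endpoint excluded

    def test_invalid_curve_rejected(self):
        with pytest.raises(ValueError):
            CalibrationCurve(1.0, 1.0, 7.5)
        with pytest.raises(ValueError):
            CalibrationCurve(0.4, 1.6, 12.0)


class TestBufferingCapacity:
    def test_van_slyke_maximum_at_pka(self):
        buf = BufferSpec(components=((2.0, 7.0),))
        assert buffering_capacity(7.0, buf) == pytest.approx(
            math.log(10) * 2.0 / 4.0, rel=1e-12
        )

    def test_hepes_mes_value(self, assay_buffer):
        # 2 mM HEPES (pKa 7.5) + 2 mM MES (pKa 6.15) at pH 7.0
        assert buffering_capacity(7.0, assay_buffer) == pytest.approx(1.34, abs=0.01)

    @pytest.mark.parametrize("ph", np.linspace(6.0, 8.0, 9).tolist())
    def test_matches_numeric_titration_derivative(self, assay_buffer, ph):
        # oracle: numeric derivative of total bound acid vs pH
        def bound_acid(p):
            return sum(
                conc * 10**-p / (10**-pka + 10**-p)
                for conc, pka in assay_buffer.components
            )

        d = 1e-4
        numeric = -(bound_acid(ph + d) - bound_acid(ph - d)) / (2 * d)
        closed = buffering_capacity(ph, assay_buffer)
        assert closed == pytest.approx(numeric, rel=1e-3)

    def test_beta_never_below_intrinsic_offset(self, assay_buffer):
        buf = BufferSpec(components=assay_buffer.components, beta0=5.0)
        grid = np.linspace(3.0, 11.0, 81)
        assert np.all(buffering_capacity(grid, buf) >= 5.0)

    def test_zero_buffering_rejected(self):
        with pytest.raises(ZeroBufferingError):
            BufferSpec(components=(), beta0=0.0)


class TestHlacSpeciation:
    def test_half_dissociation_at_pka(self):
        ctx = LactateContext(lac_out=10.0, lac_in=0.0)
        assert hlac_concentration(ctx, "out", ctx.pka_lac) == pytest.approx(5.0)

    def test_physiological_value(self):
        ctx = LactateContext(lac_out=30.0, lac_in=0.0, pka_lac=3.86)
        assert hlac_concentration(ctx, "out", 7.4) == pytest.approx(8.65e-3, rel=5e-3)

    def test_zero_total_and_monotonicity(self):
        ctx = LactateContext(lac_out=0.0, lac_in=30.0)
        assert hlac_concentration(ctx, "out", 7.0) == 0.0
        phs = np.linspace(5.5, 8.5, 30)
        vals = [hlac_concentration(ctx, "in", p) for p in phs]
        assert np.all(np.diff(vals) < 0)


def _trace(t, ph, protocol="chc_block", **kw):
    return PhTimecourse(np.asarray(t), np.asarray(ph), protocol, **kw)


class TestRateEstimation:
    def test_exact_line(self):
        t = np.linspace(0, 3, 20)
        tc = _trace(t, 7.3 - 0.01 * t)
        for method in ("ols_line", "robust_line"):
            slope, r2 = estimate_rate(tc, window=(0, 3), method=method)
            assert slope == pytest.approx(-0.01, abs=1e-12)
            assert r2 == pytest.approx(1.0)

    def test_constant_trace_r2_zero_by_convention(self):
        t = np.linspace(0, 3, 10)
        tc = _trace(t, np.full_like(t, 7.3))
        slope, r2 = estimate_rate(tc, window=(0, 3), method="ols_line")
        assert slope == 0.0 and r2 == 0.0

    def test_ols_slope_within_sampling_error(self, rng):
        t = np.linspace(0, 3, 60)
        se_analytic = 0.005 / (np.std(t) * np.sqrt(t.size))
        tc = _trace(t, 7.3 - 0.01 * t + rng.normal(0, 0.005, t.size))
        slope, _ = estimate_rate(tc, window=(0, 3), method="ols_line")
        assert abs(slope + 0.01) < 3 * se_analytic

    def test_theil_sen_resists_spike(self):
        t = np.linspace(0, 3, 30)
        y = 7.3 - 0.01 * t
        y[10] += 0.5  # single-sample artefact
        slope, _ = estimate_rate(_trace(t, y), window=(0, 3), method="robust_line")
        assert slope == pytest.approx(-0.01, abs=1e-3)

    def test_insufficient_window(self):
        t = np.linspace(0, 3, 10)
        tc = _trace(t, 7.3 - 0.01 * t)
        with pytest.raises(InsufficientDataError):
            estimate_rate(tc, window=(2.9, 2.95))


class TestFermentativeFlux:
    def test_direct_product(self):
        res = fermentative_flux(-0.01, beta=20.0)
        assert res.flux == pytest.approx(0.2)
        assert not res.alkalinizing

    def test_zero_rate(self):
        assert fermentative_flux(0.0, 20.0).flux == 0.0

    def test_alkalinizing_flagged_not_raised(self):
        res = fermentative_flux(+0.01, 20.0)
        assert res.flux < 0 and res.alkalinizing

    def test_closed_cell_conservation(self):
        # constant production J with pH-dependent beta: the time integral of
        # the inferred flux must equal the pH excursion times the path-mean
        # buffering capacity within 1%
        buf = BufferSpec(components=((10.0, 7.0),), beta0=10.0)
        j_true, dt = 0.3, 0.001
        ph = [7.4]
        for _ in range(int(20 / dt)):
            ph.append(ph[-1] - dt * j_true / buffering_capacity(ph[-1], buf))
        ph = np.array(ph)
        t = np.arange(ph.size) * dt
        # windowed flux estimates integrated over the trace
        total = 0.0
        for k in range(0, ph.size - 1000, 1000):
            sl = slice(k, k + 1001)
            slope = np.polyfit(t[sl], ph[sl], 1)[0]
            beta_mid = buffering_capacity(ph[sl].mean(), buf)
            total += fermentative_flux(slope, beta_mid).flux * (t[sl][-1] - t[sl][0])
        excursion = ph[0] - ph[-1]  # flux windows tile the whole trace
        grid = np.linspace(ph[-1], ph[0], 2001)
        beta_mean = np.trapezoid(buffering_capacity(grid, buf), grid) / excursion
        assert total == pytest.approx(excursion * beta_mean, rel=0.01)


class TestPermeability:
    def test_closed_form_chain(self):
        # beta=20, dpHi/dt=+0.05, 30 mM lactate inside at pHi 7.2 (window
        # start) -> J=1.0 mM/min, driving ~1.37e-2 mM, P ~73 min^-1
        t = np.linspace(0, 1.0, 61)
        ph = 7.2 + 0.05 * (t - 5.0 / 60.0)
        tc = _trace(t, ph, protocol="lactate_washout")
        ctx = LactateContext(lac_out=0.0, lac_in=30.0, pka_lac=3.86)
        res = permeability_from_washout(tc, ctx, beta=20.0)
        assert res.flux == pytest.approx(1.0, rel=1e-6)
        assert res.driving_force == pytest.approx(1.371e-2, rel=1e-3)
        assert res.p_hlac == pytest.approx(73.0, rel=0.01)

    def test_zero_flux_gives_zero_permeability(self):
        t = np.linspace(0, 1.0, 20)
        tc = _trace(t, np.full_like(t, 7.2), protocol="lactate_washout")
        ctx = LactateContext(lac_out=0.0, lac_in=30.0)
        assert permeability_from_washout(tc, ctx, 20.0).p_hlac == 0.0

    def test_wrong_protocol_and_degenerate_gradient(self):
        t = np.linspace(0, 1.0, 20)
        ph = 7.2 + 0.05 * t
        ctx = LactateContext(lac_out=0.0, lac_in=30.0)
        with pytest.raises(ProtocolError):
            permeability_from_washout(_trace(t, ph, "chc_block"), ctx, 20.0)
        empty = LactateContext(lac_out=0.0, lac_in=0.0)
        with pytest.raises(DegenerateGradientError):
            permeability_from_washout(
                _trace(t, ph, "lactate_washout"), empty, 20.0
            )

    def test_ion_product_formalism_proportional(self):
        t = np.linspace(0, 1.0, 61)
        ctx = LactateContext(lac_out=0.0, lac_in=30.0)
        ps = []
        for slope in (0.02, 0.04, 0.06):
            ph = 7.2 + slope * (t - 5.0 / 60.0)
            tc = _trace(t, ph, protocol="lactate_washout")
            a = permeability_from_washout(tc, ctx, 20.0, formalism="undissociated")
            b = permeability_from_washout(tc, ctx, 20.0, formalism="ion_product")
            ps.append(a.p_hlac / b.p_hlac)
        # both formalisms proportional at fixed pH_out / window-start pHi
        assert np.ptp(ps) / np.mean(ps) < 1e-6


class TestChcShift:
    def test_identical_samples(self, rng):
        x = rng.normal(7.3, 0.1, 200)
        res = chc_shift(x, x)
        assert res.median_shift == 0.0
        assert res.ks_distance == 0.0
        assert not res.major_acid_shift

    def test_offset_gaussians(self, rng):
        pre = rng.normal(7.3, 0.08, 3000)
        post = rng.normal(7.1, 0.08, 3000)
        res = chc_shift(pre, post)
        # order-statistic sampling error of the median at n=3000
        assert res.median_shift == pytest.approx(-0.2, abs=0.01)
        assert res.major_acid_shift
        assert res.left_shift_fraction == 1.0

    def test_insufficient_cells(self, rng):
        with pytest.raises(InsufficientDataError):
            chc_shift(rng.normal(size=10), rng.normal(size=100))
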