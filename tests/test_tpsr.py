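"""TPSR trace analysis: extraction, baseline, peaks, classification, map."""
import numpy as np
import pytest

from nanosites import tpsr
from nanosites.core_io import MSTimeSeries, Phase, RunMeta, ValidationError
from nanosites.synthetic_data import gen_tpsr_profile
from nanosites.tpsr import TPSRPeak


def ramp_trace(channels, n=600, t0=50.0, t1=450.0):
    meta = RunMeta()
    t_s = np.arange(n, dtype=float) * 2.0
    temp = np.linspace(t0, t1, n)
    chans = {4: np.full(n, 1.0)}
    chans.update({mz: np.asarray(v, float) for mz, v in channels.items()})
    return MSTimeSeries("r", Phase.TPSR, t_s, temp, chans, meta)


class TestExtract:
    def test_single_product(self):
        trace = ramp_trace({30: np.ones(600)})
        out = tpsr.extract_product_traces(trace)
        assert set(out) == {"HCHO"}

    def test_default_mz_assignments(self):
        trace = ramp_trace({44: np.ones(600), 45: np.ones(600),
                            60: np.ones(600), 75: np.ones(600)})
        out = tpsr.extract_product_traces(trace)
        assert set(out) == {"CO2", "DME", "methylformate", "dimethoxymethane"}

    def test_unknown_mz_ignored_with_warning(self, caplog):
        trace = ramp_trace({30: np.ones(600), 99: np.ones(600)})
        with caplog.at_level("WARNING", logger="nanosites.tpsr"):
            out = tpsr.extract_product_traces(trace)
        assert set(out) == {"HCHO"}
        assert any("mz_99" in r.message for r in caplog.records)

    def test_no_ramp_is_error(self):
        meta = RunMeta()
        n = 100
        trace = MSTimeSeries(
            "flat", Phase.TPSR, np.arange(n, dtype=float), np.full(n, 100.0),
            {30: np.ones(n), 4: np.ones(n)}, meta,
        )
        with pytest.raises(ValidationError, match="ramp"):
            tpsr.extract_product_traces(trace)


class TestBaseline:
    def test_flat_series_zeroes(self):
        temp = np.linspace(50, 450, 200)
        out = tpsr.baseline_correct(temp, np.full(200, 3.3))
        assert np.allclose(out, 0.0)

    def test_all_zero_series(self):
        temp = np.linspace(50, 450, 200)
        assert np.allclose(tpsr.baseline_correct(temp, np.zeros(200)), 0.0)

    def test_gaussian_on_linear_ramp_area_within_1pct(self):
        temp = np.linspace(50, 450, 1200)
        baseline = 0.1 + 0.002 * (temp - 50.0)
        peak = 1.0 * np.exp(-0.5 * ((temp - 250.0) / 25.0) ** 2)
        corrected = tpsr.baseline_correct(temp, baseline + peak)
        area = np.trapezoid(corrected, temp)
        true_area = 1.0 * 25.0 * np.sqrt(2 * np.pi)
        assert area == pytest.approx(true_area, rel=0.01)

    def test_too_short_series_is_error(self):
        with pytest.raises(ValidationError):
            tpsr.baseline_correct(np.arange(5.0), np.ones(5))


class TestDetectPeaks:
    def test_single_gaussian_at_259(self):
        series, _ = gen_tpsr_profile([("HCHO", 259.0, 1.0, 25.0)], seed=4)
        prof = tpsr.analyze_tpsr(series)
        hcho = [p for p in prof.peaks if p.product == "HCHO"]
        assert len(hcho) == 1
        assert hcho[0].t_max_c == pytest.approx(259.0, abs=2.0)
        # FWHM of a Gaussian is 2.355 sigma
        assert hcho[0].fwhm_c == pytest.approx(2.355 * 25.0, rel=0.1)

    def test_flat_noise_free_series_empty(self):
        temp = np.linspace(50, 450, 600)
        assert tpsr.detect_peaks(temp, np.zeros(600)) == []

    def test_two_gaussians_resolved(self):
        temp = np.linspace(50, 450, 1200)
        sig = np.exp(-0.5 * ((temp - 250) / 15.0) ** 2) + np.exp(
            -0.5 * ((temp - 350) / 15.0) ** 2
        )
        peaks = tpsr.detect_peaks(temp, sig, product="CO2", min_prominence=0.1)
        assert len(peaks) == 2
        centers = sorted(p.t_max_c for p in peaks)
        assert centers[0] == pytest.approx(250.0, abs=2.0)
        assert centers[1] == pytest.approx(350.0, abs=2.0)

    def test_isolated_gaussian_grid_recovery(self):
        """Seeded suite: centers within +-2 degC for noise <= 2%."""
        rng = np.random.default_rng(31)
        for i in range(50):
            # isolated: at least ~3 sigma away from both ramp edges
            center = float(rng.uniform(160, 350))
            sigma = float(rng.uniform(12, 35))
            noise = float(rng.uniform(0.002, 0.02))
            series, _ = gen_tpsr_profile(
                [("HCHO", center, 1.0, sigma)], seed=9000 + i, noise_sd=noise
            )
            prof = tpsr.analyze_tpsr(series)
            det = [p for p in prof.peaks if p.product == "HCHO"]
            assert det, f"case {i}: no peak found at {center}"
            best = min(det, key=lambda p: abs(p.t_max_c - center))
            assert abs(best.t_max_c - center) <= 2.0


class TestIntegrate:
    def test_zero_series(self):
        temp = np.linspace(0, 100, 50)
        assert tpsr.integrate_products({"CO2": (temp, np.zeros(50))})["CO2"] == 0.0

    def test_unit_rectangle(self):
        temp = np.linspace(0, 100, 2001)
        area = tpsr.integrate_products({"DME": (temp, np.ones(2001))})["DME"]
        assert area == pytest.approx(100.0, rel=1e-9)

    def test_gaussian_matches_closed_form(self):
        temp = np.linspace(0, 500, 4000)
        sig = 2.0 * np.exp(-0.5 * ((temp - 250) / 30.0) ** 2)
        area = tpsr.integrate_products({"HCHO": (temp, sig)})["HCHO"]
        assert area == pytest.approx(2.0 * 30.0 * np.sqrt(2 * np.pi), rel=0.01)


def peak(product, t, area=1.0):
    return TPSRPeak(product=product, t_max_c=t, height=1.0, area=area, fwhm_c=50.0)


class TestClassify:
    def test_low_temperature_co2_is_oxidizing_redox(self):
        prof = tpsr.classify_nature(
            {"CO2": 10.0, "HCHO": 1.0}, [peak("CO2", 240.0, 10.0), peak("HCHO", 230.0, 1.0)]
        )
        assert prof.label == "oxidizing-redox"
        assert prof.strength == "strong"

    def test_high_temperature_co2_is_basic(self):
        prof = tpsr.classify_nature({"CO2": 10.0}, [peak("CO2", 350.0, 10.0)])
        assert prof.label == "basic"

    def test_dominant_dme_is_acidic(self):
        prof = tpsr.classify_nature(
            {"DME": 10.0, "HCHO": 2.0, "CO2": 1.0},
            [peak("DME", 349.0, 10.0), peak("HCHO", 300.0, 2.0), peak("CO2", 410.0, 1.0)],
        )
        assert prof.label == "acidic"
        assert prof.strength == "moderate"  # 349 above the 345 degC reference

    def test_fractions_sum_to_one(self):
        prof = tpsr.classify_nature(
            {"DME": 3.0, "HCHO": 2.0, "CO2": 5.0},
            [peak("DME", 340.0, 3.0), peak("HCHO", 280.0, 2.0), peak("CO2", 350.0, 5.0)],
        )
        total = prof.fraction_acid + prof.fraction_redox + prof.fraction_basic
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_is_unreactive(self):
        prof = tpsr.classify_nature({"DME": 0.0, "HCHO": 0.0, "CO2": 0.0}, [])
        assert prof.unreactive
        assert prof.label == "unreactive"
        assert (prof.map_x, prof.map_y) == (0.0, 0.0)

    def test_uniform_intensity_scaling_invariance(self):
        areas = {"DME": 3.0, "HCHO": 2.0, "CO2": 5.0}
        peaks = [peak("DME", 340.0, 3.0), peak("HCHO", 280.0, 2.0), peak("CO2", 350.0, 5.0)]
        prof1 = tpsr.classify_nature(areas, peaks)
        scaled_areas = {k: 137.0 * v for k, v in areas.items()}
        scaled_peaks = [
            TPSRPeak(p.product, p.t_max_c, 137.0 * p.height, 137.0 * p.area, p.fwhm_c)
            for p in peaks
        ]
        prof2 = tpsr.classify_nature(scaled_areas, scaled_peaks)
        assert prof1.label == prof2.label
        assert prof1.fraction_acid == pytest.approx(prof2.fraction_acid, rel=1e-12)
        assert prof1.map_x == pytest.approx(prof2.map_x, rel=1e-12)


class TestReactivityMap:
    def test_pure_acid_limit(self):
        prof = tpsr.classify_nature({"DME": 5.0}, [peak("DME", 340.0, 5.0)])
        assert prof.map_y == pytest.approx(-1.0)

    def test_pure_basic_limit(self):
        prof = tpsr.classify_nature({"CO2": 5.0}, [peak("CO2", 360.0, 5.0)])
        assert prof.map_y == pytest.approx(1.0)

    def test_oxidation_axis_ordering(self):
        """Strong low-T CO2 (CuO-like) > narrow HCHO (ceria-like) > weak
        broad HCHO on an acidic surface (titania-like)."""
        cuo = tpsr.classify_nature(
            {"CO2": 10.0, "HCHO": 1.0}, [peak("CO2", 240.0, 10.0), peak("HCHO", 230.0, 1.0)]
        )
        ceo2 = tpsr.classify_nature(
            {"HCHO": 10.0, "DME": 1.0, "CO2": 1.5},
            [peak("HCHO", 259.0, 10.0), peak("DME", 300.0, 1.0), peak("CO2", 380.0, 1.5)],
        )
        tio2 = tpsr.classify_nature(
            {"DME": 10.0, "HCHO": 2.0, "CO2": 1.0},
            [peak("DME", 349.0, 10.0), peak("HCHO", 330.0, 2.0), peak("CO2", 410.0, 1.0)],
        )
        assert cuo.map_x > ceo2.map_x > tio2.map_x
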