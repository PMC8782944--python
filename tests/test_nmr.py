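import numpy as np
import pytest

from metaboflux import synthetic
from metaboflux.nmr import (
    FID,
    TSP,
    NMRError,
    PeakRegion,
    ReferencingError,
    Spectrum,
    apodize,
    correct,
    integrate_regions,
    process_fid,
    quantify,
    read_fid,
    read_regions,
    transform,
    write_fid,
    write_regions,
)
from metaboflux.synthetic import Acquisition, generate_fid, regions_for_library

BASE_CONC = {TSP: 3.0, "lactate": 5.0, "alanine": 1.0, "acetate": 0.5,
             "succinate": 0.52, "citrate": 0.3, "aspartate": 1.5,
             "creatine": 8.0, "choline": 0.3, "taurine": 20.0,
             "glucose": 2.0, "fumarate": 0.02, "ATP": 4.0}


def lorentzian_spectrum(centers, amplitudes, fwhm_ppm, span=(-2.0, 12.0),
                        n=40_000, referenced=True):
    ppm = np.linspace(*span, n)
    y = np.zeros(n)
    hw = fwhm_ppm / 2
    for c, a in zip(centers, amplitudes):
        y += a * hw ** 2 / ((ppm - c) ** 2 + hw ** 2)
    return Spectrum(ppm=ppm, intensity=y, referenced=referenced)


def gaussian_spectrum(centers, amplitudes, fwhm_ppm, span=(-2.0, 12.0),
                      n=40_000, referenced=True):
    # genuinely flat baseline off-peak (no Lorentzian tail pedestal)
    ppm = np.linspace(*span, n)
    y = np.zeros(n)
    sigma = fwhm_ppm / 2.3548
    for c, a in zip(centers, amplitudes):
        y += a * np.exp(-0.5 * ((ppm - c) / sigma) ** 2)
    return Spectrum(ppm=ppm, intensity=y, referenced=referenced)


def fwhm(ppm, y):
    half = y.max() / 2
    above = np.flatnonzero(y >= half)
    lo, hi = above[0], above[-1]
    x1 = np.interp(half, [y[lo - 1], y[lo]], [ppm[lo - 1], ppm[lo]])
    x2 = np.interp(half, [y[hi + 1], y[hi]], [ppm[hi + 1], ppm[hi]])
    return x2 - x1


class TestApodize:
    def test_zero_lb_identity(self):
        fid = generate_fid(BASE_CONC, noise_sd=0.0)
        out = apodize(fid, 0.0)
        np.testing.assert_array_equal(out.points, fid.points)

    def test_closed_form_scaling(self):
        acq = Acquisition(sfrq_mhz=60.0, sweep_ppm=20.0, aq_s=1.0)
        fid = FID(points=np.ones(acq.npoints, dtype=complex),
                  sfrq_mhz=60.0, sweep_ppm=20.0, aq_s=1.0)
        out = apodize(fid, 0.3)
        t_last = (acq.npoints - 1) / acq.npoints * 1.0
        assert out.points[-1].real == pytest.approx(np.exp(-np.pi * 0.3 * t_last), rel=1e-12)

    def test_negative_lb_rejected(self):
        fid = generate_fid(BASE_CONC, noise_sd=0.0)
        with pytest.raises(NMRError):
            apodize(fid, -0.1)

    def test_line_broadening_adds_to_width(self):
        # Lorentzian of natural width w apodized by lb -> spectral FWHM ~ w + lb
        lib = [synthetic.PeakLibraryEntry(TSP, 0.0, 9, 2.0)]
        fid = generate_fid({TSP: 1.0}, library=lib, noise_sd=0.0)
        for lb, expected in ((0.0, 2.0), (1.0, 3.0)):
            spec = transform(apodize(fid, lb))
            width_hz = fwhm(spec.ppm, spec.intensity.real) * fid.sfrq_mhz
            assert width_hz == pytest.approx(expected, rel=0.05)


class TestTransform:
    def test_pure_exponential_peak_position(self):
        acq = Acquisition()
        f_offset = 600.0  # Hz -> +1 ppm from carrier
        n = acq.npoints
        t = np.arange(n) * acq.aq_s / n
        fid = FID(points=np.exp(2j * np.pi * f_offset * t),
                  sfrq_mhz=acq.sfrq_mhz, sweep_ppm=acq.sweep_ppm, aq_s=acq.aq_s)
        spec = transform(fid)
        apex = spec.ppm[np.argmax(np.abs(spec.intensity))]
        assert apex == pytest.approx(acq.carrier_ppm + 1.0, abs=0.001)

    def test_zero_fid_zero_spectrum(self):
        fid = FID(points=np.zeros(600, dtype=complex), sfrq_mhz=60.0,
                  sweep_ppm=20.0, aq_s=0.5)
        assert np.all(transform(fid).intensity == 0)

    def test_parseval(self):
        fid = generate_fid(BASE_CONC, noise_sd=0.0)
        spec = transform(fid, halve_first_point=False)
        fid_energy = np.sum(np.abs(fid.points) ** 2)
        spec_energy = np.sum(np.abs(spec.intensity) ** 2) / fid.points.size
        assert spec_energy == pytest.approx(fid_energy, rel=1e-9)


class TestCorrect:
    def test_fixed_point_on_clean_spectrum(self):
        spec = gaussian_spectrum([0.0, 1.33, 3.0], [100.0, 40.0, 60.0], 0.003)
        out = correct(Spectrum(spec.ppm, spec.intensity.astype(complex), referenced=False))
        scale = np.abs(spec.intensity).max()
        np.testing.assert_allclose(out.intensity, spec.intensity, atol=1e-6 * scale)
        np.testing.assert_allclose(out.ppm, spec.ppm, atol=0.005)

    def test_linear_baseline_removed(self):
        clean = lorentzian_spectrum([0.0, 1.33], [100.0, 40.0], 0.003)
        sloped = Spectrum(
            clean.ppm,
            (clean.intensity + 5.0 + 2.0 * clean.ppm).astype(complex),
            referenced=False,
        )
        out = correct(sloped)
        regions = [PeakRegion("TSP", -0.02, 0.02, 9),
                   PeakRegion("lactate", 1.31, 1.35, 3)]
        truth = integrate_regions(clean, regions)
        got = integrate_regions(out, regions)
        for met in truth:
            assert got[met] == pytest.approx(truth[met], rel=0.01)

    def test_tsp_shifted_apex_restored(self):
        spec = lorentzian_spectrum([0.12, 1.45], [100.0, 30.0], 0.003)
        out = correct(Spectrum(spec.ppm, spec.intensity.astype(complex), referenced=False))
        apex = out.ppm[np.argmax(out.intensity)]
        assert abs(apex) <= 0.005

    def test_missing_tsp_raises(self):
        spec = lorentzian_spectrum([5.0], [100.0], 0.003)  # nothing near 0 ppm
        with pytest.raises(ReferencingError):
            correct(Spectrum(spec.ppm, spec.intensity.astype(complex), referenced=False))


class TestIntegrate:
    def test_zero_span_zero_area(self):
        spec = lorentzian_spectrum([0.0], [10.0], 0.003)
        areas = integrate_regions(spec, [PeakRegion("empty", 8.0, 9.0, 1)])
        assert areas["empty"] == pytest.approx(0.0, abs=1e-6)

    def test_split_region_additivity(self):
        spec = lorentzian_spectrum([1.0], [10.0], 0.01)
        whole = integrate_regions(spec, [PeakRegion("m", 0.8, 1.2, 1)])["m"]
        left = integrate_regions(spec, [PeakRegion("m", 0.8, 1.003, 1)])["m"]
        right = integrate_regions(spec, [PeakRegion("m", 1.003, 1.2, 1)])["m"]
        assert left + right == pytest.approx(whole, rel=1e-9)

    def test_lorentzian_analytic_integral(self):
        amplitude, fwhm_ppm = 50.0, 0.004
        hw = fwhm_ppm / 2
        spec = lorentzian_spectrum([1.0], [amplitude], fwhm_ppm, span=(0, 2), n=400_000)
        lo, hi = 1.0 - 20 * fwhm_ppm, 1.0 + 20 * fwhm_ppm
        area = integrate_regions(spec, [PeakRegion("m", lo, hi, 1)])["m"]
        analytic = amplitude * hw * np.pi
        assert area == pytest.approx(analytic, rel=0.02)

    def test_region_outside_axis_named(self):
        spec = lorentzian_spectrum([0.0], [10.0], 0.003)
        with pytest.raises(NMRError, match="far"):
            integrate_regions(spec, [PeakRegion("far", 90.0, 91.0, 1)])

    def test_unreferenced_rejected(self):
        spec = lorentzian_spectrum([0.0], [10.0], 0.003, referenced=False)
        with pytest.raises(NMRError, match="referenced"):
            integrate_regions(spec, [PeakRegion("m", -0.1, 0.1, 1)])


class TestQuantify:
    REGIONS = [PeakRegion(TSP, -0.02, 0.02, 9),
               PeakRegion("met", 0.9, 1.1, 9),
               PeakRegion("glycogen", 3.0, 3.5, 1, is_glycogen=True)]

    def test_formula_identity(self):
        res = quantify({TSP: 2.0, "met": 2.0}, self.REGIONS, tsp_nmol=5.0,
                       wet_weight_g=0.25)
        assert res.concentrations["met"] == pytest.approx(5.0 / 0.25)

    def test_all_zero_areas(self):
        res = quantify({TSP: 2.0, "met": 0.0}, self.REGIONS, tsp_nmol=5.0,
                       wet_weight_g=0.25)
        assert res.concentrations["met"] == 0.0

    def test_glycogen_skips_proton_division(self):
        res = quantify({TSP: 2.0, "glycogen": 2.0}, self.REGIONS, tsp_nmol=5.0,
                       wet_weight_g=0.25)
        # mobile-1H equivalents: ratio * 9 * tsp / weight
        assert res.concentrations["glycogen"] == pytest.approx(9 * 5.0 / 0.25)

    def test_tsp_excluded_from_output(self):
        res = quantify({TSP: 2.0, "met": 1.0}, self.REGIONS, tsp_nmol=5.0,
                       wet_weight_g=0.25)
        assert TSP not in res.concentrations

    def test_errors(self):
        with pytest.raises(NMRError, match="TSP"):
            quantify({TSP: 0.0, "met": 1.0}, self.REGIONS, 5.0, 0.25)
        with pytest.raises(NMRError, match="weight"):
            quantify({TSP: 1.0, "met": 1.0}, self.REGIONS, 5.0, 0.0)


class TestFullChain:
    def test_round_trip_within_2_percent(self):
        fid = generate_fid(BASE_CONC, noise_sd=0.0)
        regions = regions_for_library(glycogen=frozenset())
        res = process_fid(fid, regions, tsp_nmol=0.3, wet_weight_g=0.1)
        for met, value in res.concentrations.items():
            assert value == pytest.approx(BASE_CONC[met], rel=0.02), met

    def test_linearity_in_concentration(self):
        regions = regions_for_library(glycogen=frozenset())
        res1 = process_fid(generate_fid(BASE_CONC, noise_sd=0.0), regions,
                           tsp_nmol=0.3, wet_weight_g=0.1)
        doubled = {k: 2 * v for k, v in BASE_CONC.items()}
        res2 = process_fid(generate_fid(doubled, noise_sd=0.0), regions,
                           tsp_nmol=0.6, wet_weight_g=0.1)
        for met in res1.concentrations:
            assert res2.concentrations[met] == pytest.approx(
                2 * res1.concentrations[met], rel=0.01)

    def test_tsp_amount_self_consistency(self):
        regions = regions_for_library(glycogen=frozenset())
        results = []
        for tsp_amount in (0.2, 0.5):
            conc = dict(BASE_CONC)
            conc[TSP] = tsp_amount / 0.1
            fid = generate_fid(conc, noise_sd=0.0)
            results.append(process_fid(fid, regions, tsp_nmol=tsp_amount,
                                       wet_weight_g=0.1).concentrations)
        for met in results[0]:
            assert results[0][met] == pytest.approx(results[1][met], rel=0.02)

    def test_carrier_shift_invariance(self):
        regions = regions_for_library(glycogen=frozenset())
        base = process_fid(generate_fid(BASE_CONC, noise_sd=0.0), regions,
                           tsp_nmol=0.3, wet_weight_g=0.1).concentrations
        shifted_acq = Acquisition(carrier_ppm=4.95)
        shifted = process_fid(
            generate_fid(BASE_CONC, acquisition=shifted_acq, noise_sd=0.0),
            regions, tsp_nmol=0.3, wet_weight_g=0.1).concentrations
        for met in base:
            assert shifted[met] == pytest.approx(base[met], rel=0.01)

    def test_deterministic(self):
        regions = regions_for_library(glycogen=frozenset())
        fid = generate_fid(BASE_CONC, noise_sd=0.0)
        a = process_fid(fid, regions, tsp_nmol=0.3, wet_weight_g=0.1)
        b = process_fid(fid, regions, tsp_nmol=0.3, wet_weight_g=0.1)
        assert a.concentrations == b.concentrations


class TestIO:
    def test_fid_text_round_trip(self, tmp_path):
        acq = Acquisition(sfrq_mhz=60.0, sweep_ppm=20.0, aq_s=0.5)
        fid = generate_fid({TSP: 1.5, "lactate": 2.5}, acquisition=acq,
                           noise_sd=0.01, seed=3)
        path = tmp_path / "sample.fid"
        write_fid(fid, path)
        back = read_fid(path)
        np.testing.assert_array_equal(back.points, fid.points)
        assert back.sfrq_mhz == fid.sfrq_mhz
        assert back.carrier_ppm == fid.carrier_ppm

    def test_region_file_round_trip(self, tmp_path):
        regions = regions_for_library()
        path = tmp_path / "regions.csv"
        write_regions(regions, path)
        assert read_regions(path) == regions

    def test_inconsistent_fid_metadata_rejected(self):
        with pytest.raises(NMRError, match="dwell|inconsistent"):
            FID(points=np.ones(100, dtype=complex), sfrq_mhz=600.0,
                sweep_ppm=20.0, aq_s=2.6)
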