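"""Spectrum processing, quenching statistics and Beer–Lambert arithmetic."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anchordepth import fluor as F
from anchordepth import synth


def gaussian_spectrum(center=470.0, amp=1.0, baseline=0.0, **cond):
    wl = np.arange(420.0, 601.0, 2.0)
    return F.EmissionSpectrum(wl, amp * np.exp(-0.5 * ((wl - center) / 28.0) ** 2) + baseline,
                              **cond)


# ------------------------------------------------------- background/normalize

def test_background_subtraction_cases():
    s = gaussian_spectrum()
    zero = s.with_intensities(np.zeros_like(s.intensities))
    assert np.allclose(F.subtract_background(s, s).intensities, 0.0)
    assert np.allclose(F.subtract_background(s, zero).intensities, s.intensities)
    planted = s.with_intensities(s.intensities + 0.25)
    recovered = F.subtract_background(planted, planted.with_intensities(
        np.full_like(s.intensities, 0.25)))
    assert np.allclose(recovered.intensities, s.intensities, atol=1e-15)


def test_background_grid_mismatch_error():
    s = gaussian_spectrum()
    other = F.EmissionSpectrum(np.arange(400.0, 581.0, 2.0), np.zeros(91))
    with pytest.raises(ValueError, match="grid"):
        F.subtract_background(s, other)


def test_normalize_to_unbound_peak_and_ratios():
    unbound = gaussian_spectrum(amp=2.0)
    double = gaussian_spectrum(amp=4.0)
    out = F.normalize_to_unbound({"u": unbound, "d": double}, unbound)
    assert out["u"].intensities.max() == pytest.approx(1.0)
    assert out["d"].intensities.max() == pytest.approx(2.0)
    ratio = out["d"].intensities[30] / out["u"].intensities[30]
    assert ratio == pytest.approx(2.0, abs=1e-12)
    with pytest.raises(ValueError):
        F.normalize_to_unbound({"u": unbound}, unbound.with_intensities(
            np.zeros_like(unbound.intensities)))


# ----------------------------------------------------------------- integrals

def test_integration_constant_and_zero():
    wl = np.arange(420.0, 601.0, 2.0)
    const = F.EmissionSpectrum(wl, np.ones_like(wl))
    assert F.integrated_intensity(const) == pytest.approx(180.0)
    assert F.integrated_intensity(const.with_intensities(np.zeros_like(wl))) == 0.0


def test_gaussian_integral_matches_analytic_area():
    wl = np.arange(300.0, 701.0, 0.5)
    sigma, amp = 20.0, 3.0
    s = F.EmissionSpectrum(wl, amp * np.exp(-0.5 * ((wl - 500.0) / sigma) ** 2))
    analytic = amp * sigma * np.sqrt(2 * np.pi)
    assert F.integrated_intensity(s) == pytest.approx(analytic, rel=0.005)


def test_integration_range_errors():
    s = gaussian_spectrum()
    with pytest.raises(ValueError):
        F.integrated_intensity(s, (700.0, 750.0))


# ----------------------------------------------------------------- quenching

@pytest.mark.parametrize(
    "f_sl,f_ctrl,expected,negative",
    [(0.70, 1.00, 30.0, False), (1.0, 1.0, 0.0, False), (1.10, 1.00, -10.0, True)],
)
def test_quenching_efficiency_values(f_sl, f_ctrl, expected, negative):
    q = F.quenching_efficiency(f_sl, f_ctrl)
    assert q.efficiency == pytest.approx(expected, abs=1e-12)
    assert q.negative_flag is negative


def test_quenching_control_must_be_positive():
    with pytest.raises(ValueError):
        F.quenching_efficiency(1.0, 0.0)


@settings(derandomize=True, max_examples=40)
@given(st.floats(0.01, 100.0), st.floats(0.01, 100.0), st.floats(0.001, 1000.0))
def test_quenching_scale_invariance(f_sl, f_ctrl, c):
    base = F.quenching_efficiency(f_sl, f_ctrl).efficiency
    scaled = F.quenching_efficiency(c * f_sl, c * f_ctrl).efficiency
    assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)
    assert base <= 100.0


def test_quenching_strictly_decreasing_in_signal():
    effs = [F.quenching_efficiency(f, 1.0).efficiency for f in (0.2, 0.5, 0.9, 1.3)]
    assert all(a > b for a, b in zip(effs, effs[1:]))


# ------------------------------------------------------------------ λmax

def test_lambda_max_on_grid_triangle():
    wl = np.arange(420.0, 601.0, 2.0)
    tri = F.EmissionSpectrum(wl, np.maximum(0.0, 1.0 - np.abs(wl - 470.0) / 30.0))
    assert F.lambda_max(tri) == pytest.approx(470.0)


def test_lambda_max_subgrid_precision():
    s = gaussian_spectrum(center=467.3)
    assert F.lambda_max(s) == pytest.approx(467.3, abs=0.3)


def test_lambda_max_translation_equivariance():
    s = gaussian_spectrum(center=470.8)
    shifted = F.EmissionSpectrum(s.wavelengths, np.roll(s.intensities, 1))
    # rolling by one grid point moves the peak by exactly one step
    assert F.lambda_max(shifted) - F.lambda_max(s) == pytest.approx(2.0, abs=1e-6)


def test_lambda_max_centroid_robust_to_point_noise():
    rng = np.random.default_rng(9)
    s = gaussian_spectrum(center=467.3)
    noisy = s.with_intensities(s.intensities * (1 + rng.normal(0, 0.01, s.intensities.shape)))
    assert F.lambda_max(noisy, method="centroid") == pytest.approx(467.3, abs=1.0)


def test_lambda_max_flat_spectrum_error():
    wl = np.arange(420.0, 601.0, 2.0)
    with pytest.raises(ValueError, match="flat"):
        F.lambda_max(F.EmissionSpectrum(wl, np.ones_like(wl)))


def test_lambda_max_edge_peak_warns_and_returns_edge(caplog):
    wl = np.arange(420.0, 601.0, 2.0)
    s = F.EmissionSpectrum(wl, np.linspace(0, 1, len(wl)))
    assert F.lambda_max(s) == 600.0


# ------------------------------------------------------------------ shifts

def test_classify_shift_cases():
    unbound = gaussian_spectrum(center=470.0, state="unbound")
    same = gaussian_spectrum(center=470.0, state="dark")
    blue12 = gaussian_spectrum(center=458.0, state="dark")
    blue5 = gaussian_spectrum(center=465.0, state="dark")
    assert F.classify_shift(unbound, same).delta_nm == pytest.approx(0.0, abs=1e-6)
    assert not F.classify_shift(unbound, same).significant
    assert F.classify_shift(unbound, blue12).significant
    assert not F.classify_shift(unbound, blue5).significant


def test_classify_shift_antisymmetric():
    a = gaussian_spectrum(center=470.0)
    b = gaussian_spectrum(center=461.0)
    assert F.classify_shift(a, b).delta_nm == pytest.approx(
        -F.classify_shift(b, a).delta_nm, abs=1e-9
    )


# ------------------------------------------------------------ concentrations

def test_concentration_arithmetic():
    rec = F.AbsorbanceRecord(a280=0.03076, a380=0.010, da500=0.204)
    out = F.concentrations(rec)
    assert out.rhodopsin_uM == pytest.approx(5.0)
    assert out.bimane_uM == pytest.approx(2.0)
    assert out.arrestin_uM == pytest.approx(1.0)
    assert out.labeling_efficiency == pytest.approx(2.0)


def test_concentration_no_label_limit_and_errors():
    out = F.concentrations(F.AbsorbanceRecord(a280=0.02076, a380=0.0, da500=0.0))
    assert out.labeling_efficiency == 0.0
    assert out.arrestin_uM == pytest.approx(1.0)
    with pytest.raises(ValueError):
        F.concentrations(F.AbsorbanceRecord(a280=0.01, a380=0.02, da500=0.0))


def test_concentration_path_length_scaling():
    out = F.concentrations(F.AbsorbanceRecord(0.03076, 0.010, 0.204, path_cm=2.0))
    assert out.rhodopsin_uM == pytest.approx(2.5)


# --------------------------------------------------------------- end-to-end

def test_planted_quenching_recovered_through_pipeline():
    spec = synth.SpectrumSpec(noise=0.0, seed=0)
    spectra, background, truth = synth.make_spectrum_set(spec)
    quench, shifts, table = F.analyze_spectrum_set(spectra.values(), background=background)
    for q in quench:
        assert q.efficiency == pytest.approx(truth.planted_q[(q.state, q.quencher)], abs=1e-9)
    for sh in shifts:
        assert sh.delta_nm == pytest.approx(truth.planted_shift[sh.state], abs=0.3)


def test_peak_statistic_switch_matches_at_zero_noise():
    spec = synth.SpectrumSpec(noise=0.0, seed=0)
    spectra, background, truth = synth.make_spectrum_set(spec)
    quench, _, _ = F.analyze_spectrum_set(spectra.values(), background=background,
                                          use_peak=True)
    for q in quench:
        assert q.efficiency == pytest.approx(truth.planted_q[(q.state, q.quencher)], abs=1e-9)


def test_spectrum_csv_round_trip(tmp_path):
    s = gaussian_spectrum(site=342, state="dark", lipid="doxyl")
    path = tmp_path / "s.csv"
    F.write_spectrum_csv(path, s)
    back = F.read_spectrum_csv(path)
    assert (back.site, back.state, back.lipid) == (342, "dark", "doxyl")
    assert np.allclose(back.wavelengths, s.wavelengths)
    assert np.allclose(back.intensities, s.intensities, atol=1e-9)
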