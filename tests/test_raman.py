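import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memphys.raman import (
    RamanSpectrum,
    UnusableSpectrumError,
    ch_stretch_ratios,
    preprocess_spectrum,
    subtract_serotonin_reference,
)
from memphys.synthetic import gen_raman_spectrum, gen_serotonin_reference

GRID = np.arange(1400.0, 3100.0, 0.5)


def _band(center, fwhm, height, grid=GRID, truncate=None):
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    y = height * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    if truncate is not None:
        y[np.abs(grid - center) > truncate * sigma] = 0.0
    return y


def _three_bands(h2850=1.0, h2890=0.8, h2930=0.5, truncate=None):
    return (
        _band(2850, 12, h2850, truncate=truncate)
        + _band(2890, 12, h2890, truncate=truncate)
        + _band(2930, 12, h2930, truncate=truncate)
    )


class TestPreprocess:
    def test_sloped_baseline_removed(self):
        y = _three_bands() + 0.2 + 2e-4 * (GRID - GRID[0])
        out = preprocess_spectrum(RamanSpectrum(wavenumber=GRID, intensity=y))
        flank = (GRID > 2000) & (GRID < 2400)  # band-free region
        assert np.mean(out.intensity[flank]) < 0.01 * out.intensity.max()
        assert out.window_max(2840, 2860) == pytest.approx(1.0)

    def test_idempotent_on_clean_normalized_spectrum(self):
        y = _three_bands(truncate=4.0)  # compact support, zero flanks
        s = preprocess_spectrum(RamanSpectrum(wavenumber=GRID, intensity=y))
        s2 = preprocess_spectrum(s)
        assert np.allclose(s2.intensity, s.intensity, atol=1e-9)

    def test_flat_spectrum_rejected(self):
        with pytest.raises(UnusableSpectrumError):
            preprocess_spectrum(
                RamanSpectrum(wavenumber=GRID, intensity=np.full_like(GRID, 3.0))
            )

    def test_missing_2850_band_rejected(self):
        y = _band(1540, 14, 1.0)  # only the indole band
        with pytest.raises(UnusableSpectrumError):
            preprocess_spectrum(RamanSpectrum(wavenumber=GRID, intensity=y))


class TestSubtraction:
    def test_known_mixture_restored(self):
        """Sample = lipid + 0.3 * serotonin reference: subtraction restores
        the lipid-only C-H window within 1% (up to overall normalization)."""
        ref_raw = gen_serotonin_reference(GRID)
        lipid = _three_bands()
        mix = lipid + 0.3 * ref_raw.intensity
        s = preprocess_spectrum(RamanSpectrum(wavenumber=GRID, intensity=mix))
        ref = preprocess_spectrum(ref_raw)
        out = subtract_serotonin_reference(s, ref)
        ch = (GRID >= 2800) & (GRID <= 3000)
        got = out.intensity[ch] / out.intensity[ch].max()
        want = lipid[ch] / lipid[ch].max()
        assert np.allclose(got, want, atol=0.01)

    def test_zero_indole_band_is_noop(self):
        lipid = _three_bands(truncate=4.0)
        s = preprocess_spectrum(RamanSpectrum(wavenumber=GRID, intensity=lipid))
        ref = preprocess_spectrum(gen_serotonin_reference(GRID))
        out = subtract_serotonin_reference(s, ref)
        assert out.meta["serotonin_scale_k"] == 0.0
        assert np.allclose(out.intensity, s.intensity)

    def test_self_subtraction_vanishes(self):
        ref = preprocess_spectrum(gen_serotonin_reference(GRID))
        out = subtract_serotonin_reference(ref, ref)
        assert np.allclose(out.intensity, 0.0, atol=1e-9)

    def test_reference_without_indole_band_rejected(self):
        bad = preprocess_spectrum(
            RamanSpectrum(wavenumber=GRID, intensity=_three_bands(truncate=4.0))
        )
        s = preprocess_spectrum(
            RamanSpectrum(wavenumber=GRID, intensity=_three_bands())
        )
        with pytest.raises(UnusableSpectrumError):
            subtract_serotonin_reference(s, bad)

    @given(w=st.floats(0.05, 1.0))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_exact_for_linear_combinations(self, w):
        """For any mixing weight in (0, 1] the subtraction restores the
        lipid-only band ratios."""
        ref_raw = gen_serotonin_reference(GRID)
        lipid = _three_bands()
        mix = lipid + w * ref_raw.intensity
        s = preprocess_spectrum(RamanSpectrum(wavenumber=GRID, intensity=mix))
        ref = preprocess_spectrum(ref_raw)
        out = subtract_serotonin_reference(s, ref)
        r = ch_stretch_ratios(out)
        assert r.r_2930_2890 == pytest.approx(0.5 / 0.8, rel=0.01)


class TestRatios:
    def test_known_heights(self):
        """Band heights (1.0, 0.8, 0.5) give I2930/I2890 = 0.625 and
        I2930/I2850 = 0.5."""
        s = preprocess_spectrum(
            RamanSpectrum(wavenumber=GRID, intensity=_three_bands())
        )
        r = ch_stretch_ratios(s)
        assert r.r_2930_2890 == pytest.approx(0.625, rel=1e-3)
        assert r.r_2930_2850 == pytest.approx(0.5, rel=1e-3)

    def test_equal_heights_give_unit_ratios(self):
        s = preprocess_spectrum(
            RamanSpectrum(wavenumber=GRID, intensity=_three_bands(1.0, 1.0, 1.0))
        )
        r = ch_stretch_ratios(s)
        assert r.r_2930_2890 == pytest.approx(1.0, rel=1e-3)
        assert r.r_2930_2850 == pytest.approx(1.0, rel=1e-3)

    def test_control_vs_itself_unit_relative_ratio(self):
        s = preprocess_spectrum(
            RamanSpectrum(wavenumber=GRID, intensity=_three_bands())
        )
        r0 = ch_stretch_ratios(s)
        r = ch_stretch_ratios(s, control_ratio=r0.r_2930_2890)
        assert r.rel_ratio == pytest.approx(1.0)

    def test_global_scaling_invariance(self):
        y = _three_bands() + 0.1
        r1 = ch_stretch_ratios(
            preprocess_spectrum(RamanSpectrum(wavenumber=GRID, intensity=y))
        )
        r2 = ch_stretch_ratios(
            preprocess_spectrum(RamanSpectrum(wavenumber=GRID, intensity=7.3 * y))
        )
        assert r2.r_2930_2890 == pytest.approx(r1.r_2930_2890, rel=1e-9)
        assert r2.r_2930_2850 == pytest.approx(r1.r_2930_2850, rel=1e-9)

    def test_empty_window_rejected(self):
        grid = np.arange(1400.0, 2000.0, 0.5)
        s = RamanSpectrum(wavenumber=grid, intensity=_band(1540, 14, 1.0, grid=grid))
        with pytest.raises(UnusableSpectrumError):
            ch_stretch_ratios(s)

    def test_voigt_band_method_agrees_on_clean_bands(self):
        s = preprocess_spectrum(
            RamanSpectrum(wavenumber=GRID, intensity=_three_bands())
        )
        r = ch_stretch_ratios(s, band_method="voigt")
        assert r.r_2930_2890 == pytest.approx(0.625, rel=0.02)


def test_relative_ratio_monotone_in_dose(em):
    """The recovered I/Io rises monotonically with serotonin dose in the
    generator's disorder signature (2930 up, 2890 down)."""
    ref = None
    rels = []
    r0 = None
    for conc in (0.0, 1.0, 5.0, 10.0, 20.0, 40.0):
        s, ref_raw = gen_raman_spectrum(em, "DOPC", conc, seed=1, noise=0.0)
        sp = preprocess_spectrum(s)
        ref = preprocess_spectrum(ref_raw)
        out = subtract_serotonin_reference(sp, ref)
        r = ch_stretch_ratios(out)
        if r0 is None:
            r0 = r.r_2930_2890
        rels.append(r.r_2930_2890 / r0)
    assert all(b > a - 1e-9 for a, b in zip(rels, rels[1:]))
    assert rels[-1] > 1.2
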