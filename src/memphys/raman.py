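"""Raman C-H stretch band-ratio analysis for lipid acyl-chain order.

The 2800-3000 cm^-1 window of a lipid Raman spectrum carries three bands:
~2850 cm^-1 (methylene symmetric stretch), ~2890 cm^-1 (methylene
antisymmetric stretch) and ~2930 cm^-1 (terminal methyl symmetric stretch).
The intensity ratios I2930/I2890 and I2930/I2850 increase with acyl-chain
conformational disorder and looser lateral packing, so they serve as bulk
order parameters.

Serotonin itself scatters in this window, so before ratio analysis its
contribution is removed by scaled subtraction of a serotonin reference
spectrum; the scale is anchored on the ~1540 cm^-1 indole ring-stretching
band, which the lipid does not have.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: analysis windows (cm^-1): band center -> (lo, hi)
BAND_WINDOWS = {
    2850: (2840.0, 2860.0),
    2890: (2880.0, 2900.0),
    2930: (2920.0, 2940.0),
}
INDOLE_WINDOW = (1520.0, 1560.0)
NORM_WINDOW = BAND_WINDOWS[2850]


class UnusableSpectrumError(ValueError):
    """Spectrum lacks the bands required for the analysis."""


@dataclass
class RamanSpectrum:
    """(wavenumber, intensity) trace with a sample label."""

    wavenumber: np.ndarray  # cm^-1, increasing
    intensity: np.ndarray  # a.u.
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumber.shape != self.intensity.shape:
            raise ValueError("wavenumber and intensity must have equal length")
        if np.any(np.diff(self.wavenumber) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")

    def window(self, lo: float, hi: float) -> np.ndarray:
        m = (self.wavenumber >= lo) & (self.wavenumber <= hi)
        if not m.any():
            raise UnusableSpectrumError(f"window {lo}-{hi} cm^-1 empty on grid")
        return self.intensity[m]

    def window_max(self, lo: float, hi: float) -> float:
        return float(self.window(lo, hi).max())


@dataclass
class CHRatios:
    """Band intensities and order ratios of the C-H stretching region."""

    I2850: float
    I2890: float
    I2930: float
    r_2930_2890: float
    r_2930_2850: float
    rel_ratio: float | None = None  # I/Io vs control


def _masked_polyfit_baseline(
    x: np.ndarray, y: np.ndarray, degree: int, n_iter: int = 20
) -> np.ndarray:
    """Degree-``degree`` polynomial baseline through the non-peak regions,
    found by iteratively refitting on points at or below the current fit
    (modpoly-style)."""
    mask = np.ones_like(y, dtype=bool)
    coef = np.polyfit(x, y, degree)
    for _ in range(n_iter):
        base = np.polyval(coef, x)
        resid = y - base
        sigma = np.std(resid[mask]) if mask.any() else 0.0
        new_mask = resid <= max(sigma, 1e-12)
        if new_mask.sum() < degree + 2:
            break
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
        coef = np.polyfit(x[mask], y[mask], degree)
    return np.polyval(coef, x)


def preprocess_spectrum(
    s: RamanSpectrum, baseline_degree: int = 3, min_contrast: float = 1e-6
) -> RamanSpectrum:
    """Baseline-correct and normalize a raw spectrum.

    A degree-3 polynomial fitted to the non-peak regions is subtracted,
    negative residuals are clipped at zero, and the trace is rescaled so the
    local maximum in the 2840-2860 cm^-1 window equals 1.  A spectrum with
    no discernible 2850 band raises :class:`UnusableSpectrumError`.
    """
    x, y = s.wavenumber, s.intensity
    if np.ptp(y) <= min_contrast * max(np.abs(y).max(), 1.0):
        raise UnusableSpectrumError("flat spectrum: no bands present")
    base = _masked_polyfit_baseline(x, y, baseline_degree)
    corrected = np.clip(y - base, 0.0, None)
    out = replace(s, intensity=corrected)
    try:
        peak = out.window_max(*NORM_WINDOW)
    except UnusableSpectrumError:
        raise UnusableSpectrumError("grid does not cover the 2850 cm^-1 band")
    if peak <= min_contrast * max(corrected.max(), 1.0) or peak <= 0:
        raise UnusableSpectrumError("no discernible 2850 cm^-1 band")
    return replace(out, intensity=corrected / peak)


def subtract_serotonin_reference(
    s: RamanSpectrum, ref: RamanSpectrum, clip: bool = True
) -> RamanSpectrum:
    """Remove serotonin's spectral contribution from a sample spectrum.

    Both spectra must be preprocessed and share their grid.  The reference
    is scaled so its 1540 cm^-1 indole band matches the sample's, then
    subtracted; negative residuals are clipped at zero (the negative mass
    fraction is reported in ``meta["negative_residual_fraction"]`` as a QC
    metric).
    """
    if not np.array_equal(s.wavenumber, ref.wavenumber):
        raise ValueError("sample and reference must share a wavenumber grid")
    ref_ind = ref.window_max(*INDOLE_WINDOW)
    if ref_ind <= 1e-9 * max(ref.intensity.max(), 1.0):
        raise UnusableSpectrumError(
            "reference lacks a 1540 cm^-1 indole band: invalid reference"
        )
    k = s.window_max(*INDOLE_WINDOW) / ref_ind
    diff = s.intensity - k * ref.intensity
    neg = float(-diff[diff < 0].sum()) if (diff < 0).any() else 0.0
    total = float(np.abs(diff).sum()) or 1.0
    out = np.clip(diff, 0.0, None) if clip else diff
    meta = dict(s.meta)
    meta["serotonin_scale_k"] = float(k)
    meta["negative_residual_fraction"] = neg / total
    return replace(s, intensity=out, meta=meta)


def _band_intensity_max(s: RamanSpectrum, center: int) -> float:
    return s.window_max(*BAND_WINDOWS[center])


def _band_intensity_voigt(s: RamanSpectrum, center: int) -> float:
    """Alternative band estimate: height of a fitted pseudo-Voigt profile
    on a widened window around the band center."""
    from scipy.optimize import curve_fit

    lo, hi = BAND_WINDOWS[center]
    m = (s.wavenumber >= lo - 10) & (s.wavenumber <= hi + 10)
    x, y = s.wavenumber[m], s.intensity[m]

    def pv(x, h, x0, w, eta):
        g = np.exp(-4 * np.log(2) * ((x - x0) / w) ** 2)
        l = 1.0 / (1.0 + 4 * ((x - x0) / w) ** 2)
        return h * ((1 - eta) * g + eta * l)

    p0 = [float(y.max()), float(x[np.argmax(y)]), 15.0, 0.3]
    try:
        popt, _ = curve_fit(
            pv, x, y, p0=p0,
            bounds=([0, lo, 2, 0], [np.inf, hi, 80, 1]), maxfev=5000,
        )
        return float(popt[0])
    except RuntimeError:
        return float(y.max())


def ch_stretch_ratios(
    s: RamanSpectrum,
    control_ratio: float | None = None,
    band_method: str = "max",
) -> CHRatios:
    """C-H stretch band intensities and order ratios.

    Band intensities are windowed maxima (2840-2860, 2880-2900, 2920-2940
    cm^-1) by default, or fitted pseudo-Voigt heights with
    ``band_method="voigt"``.  When ``control_ratio`` is given, ``rel_ratio``
    is I2930/I2890 divided by that control value (I/Io).
    """
    pick = _band_intensity_max if band_method == "max" else _band_intensity_voigt
    i2850 = pick(s, 2850)
    i2890 = pick(s, 2890)
    i2930 = pick(s, 2930)
    if i2890 <= 0 or i2850 <= 0:
        raise UnusableSpectrumError("reference C-H bands have zero intensity")
    r_tg = i2930 / i2890
    r_ts = i2930 / i2850
    rel = r_tg / control_ratio if control_ratio else None
    return CHRatios(
        I2850=i2850, I2890=i2890, I2930=i2930,
        r_2930_2890=r_tg, r_2930_2850=r_ts, rel_ratio=rel,
    )
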