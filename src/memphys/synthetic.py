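"""Seeded synthetic-data generators for every pipeline input.

The generators emulate a factorial study of serotonin acting on three model
membranes (DOPC, DOPC/DOPS 10:1, DOPC/SM/Chol 1:1:0.2) at six serotonin
doses (0, 1, 5, 10, 20, 40 mM).  Dose responses saturate,

    effect(c) = emax * c / (c + c50),       c50 = 10 mM by default,

mirroring the observed leveling-off of the serotonin effects at high
concentration.  Control levels are the measured control values of each
assay; emax values are set so the 40 mM condition reproduces the observed
high-dose changes.  They are illustrative generator settings, not estimated
quantities.

Every generator is a pure function of (parameters, seed) and records its
ground truth in the returned object's metadata, so round-trip recovery
through the analysis modules is testable without instrument data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Circle, DropletPairGeometry, geometry_from_diameters_and_theta
from .calorimetry import Thermogram
from .osmosis import (
    DEFAULT_OSMOLALITY_MOSM_KG,
    DropletTimeSeries,
    OsmoticState,
    simulate_osmosis,
)
from .raman import RamanSpectrum
from .stats import StudyTable

MEMBRANES = ("DOPC", "DOPC/DOPS", "DOPC/SM/Chol")
CONCENTRATIONS = (0.0, 1.0, 5.0, 10.0, 20.0, 40.0)  # mM

OBSERVABLES = ("Pf", "gamma_m", "theta", "Tm", "dH", "fwhm", "ratio")


@dataclass
class EffectModel:
    """Control levels and saturating dose-response effects per membrane.

    ``controls[mem][obs]`` is the 0 mM level of observable ``obs``;
    ``emax[mem][obs]`` the saturating effect (relative for Pf/gamma_m/dH/
    fwhm/ratio, additive in degrees for theta and in C for Tm);
    ``noise_sd[obs]`` the replicate noise SD (relative, except Tm: C).
    """

    c50: float = 10.0  # mM
    controls: dict = field(default_factory=lambda: {
        "DOPC": {
            "Pf": 73.0, "gamma_m": 1.125, "theta": 31.20,
            "Tm": -16.68, "dH": 8.34, "fwhm": 1.50, "ratio": 0.625,
        },
        "DOPC/DOPS": {
            "Pf": 62.0, "gamma_m": 1.15, "theta": 30.0,
            "Tm": -15.88, "dH": 9.10, "fwhm": 0.95, "ratio": 0.625,
        },
        "DOPC/SM/Chol": {
            "Pf": 67.0, "gamma_m": 1.185, "theta": 23.96,
            "Tm": -18.67, "dH": 2.67, "fwhm": 2.73, "ratio": 0.625,
        },
    })
    emax: dict = field(default_factory=lambda: {
        # scaled so the 40 mM dose (f = 0.8 at c50 = 10) matches the
        # observed high-dose changes of each assay
        "DOPC": {
            "Pf": 0.171, "gamma_m": -0.512, "theta": 21.9,
            "Tm": -1.375, "dH": -0.454, "fwhm": 0.841, "ratio": 0.35,
        },
        "DOPC/DOPS": {
            "Pf": 0.242, "gamma_m": -0.60, "theta": 18.0,
            "Tm": -3.875, "dH": -0.797, "fwhm": 3.67, "ratio": 0.40,
        },
        "DOPC/SM/Chol": {
            "Pf": 0.243, "gamma_m": -0.799, "theta": 15.0,
            "Tm": -7.34, "dH": -1.04, "fwhm": 1.27, "ratio": 0.20,
        },
    })
    noise_sd: dict = field(default_factory=lambda: {
        "Pf": 0.035, "gamma_m": 0.02, "theta": 0.01,
        "Tm": 0.08, "dH": 0.04, "fwhm": 0.04, "ratio": 0.03,
    })

    def dose_factor(self, conc: float) -> float:
        return conc / (conc + self.c50)

    def level(self, membrane: str, obs: str, conc: float) -> float:
        """Noise-free value of ``obs`` for the given condition."""
        if membrane not in self.controls:
            raise KeyError(f"unknown membrane label {membrane!r}")
        if obs not in self.controls[membrane]:
            raise KeyError(f"unknown observable {obs!r}")
        base = self.controls[membrane][obs]
        eff = self.emax[membrane][obs] * self.dose_factor(conc)
        if obs in ("Tm", "theta"):  # additive effects
            return base + eff
        return max(base * (1.0 + eff), 0.05 * abs(base))


# ---------------------------------------------------------------------------
# droplet permeability traces


def gen_droplet_timeseries(
    em: EffectModel,
    membrane: str = "DOPC",
    conc: float = 0.0,
    seed: int = 0,
    d0_um: float = 100.0,
    osmolality_mOsm_kg: float = DEFAULT_OSMOLALITY_MOSM_KG,
    t_max_s: float = 60.0,
    dt_s: float = 1.0,
    noise: float = 0.005,
) -> DropletTimeSeries:
    """Forward-simulate a droplet-pair shrink/swell trace for the condition
    and apply multiplicative radius noise.  Ground-truth Pf, the contact
    angle and the noise level are recorded in the metadata."""
    pf = em.level(membrane, "Pf", conc)
    theta = em.level(membrane, "theta", 0.0)  # geometry set at bilayer formation
    geom = geometry_from_diameters_and_theta(d0_um, d0_um, theta)
    state = OsmoticState.from_diameters(
        d1=d0_um, d2=d0_um, A=geom.Ab, osmolality1_mOsm_kg=osmolality_mOsm_kg
    )
    t = np.arange(0.0, t_max_s + 0.5 * dt_s, dt_s)
    ts = simulate_osmosis(state, pf, t)
    rng = np.random.default_rng(seed)
    d1 = ts.d1 * (1.0 + noise * rng.standard_normal(len(t)))
    d2 = ts.d2 * (1.0 + noise * rng.standard_normal(len(t)))
    return DropletTimeSeries(
        t=t,
        d1=d1,
        d2=d2,
        A=ts.A,
        osmolality_hyper=osmolality_mOsm_kg,
        temperature=30.0,
        meta={
            "Pf_true": pf,
            "theta_deg": theta,
            "membrane": membrane,
            "serotonin_mM": conc,
            "noise": noise,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# DSC thermograms


def pseudo_voigt(x: np.ndarray, center: float, fwhm: float, area: float,
                 eta: float = 0.15) -> np.ndarray:
    """Unit-area pseudo-Voigt profile scaled to ``area``: eta * Lorentzian +
    (1 - eta) * Gaussian, both with the same fwhm."""
    hwhm = fwhm / 2.0
    lor = (hwhm / math.pi) / ((x - center) ** 2 + hwhm**2)
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    gau = np.exp(-0.5 * ((x - center) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    return area * (eta * lor + (1.0 - eta) * gau)


def gen_thermogram(
    em: EffectModel,
    membrane: str = "DOPC",
    conc: float = 0.0,
    seed: int = 0,
    T_lo: float = -40.0,
    T_hi: float = -5.0,
    dT: float = 0.02,
    baseline_slope: float = 0.01,
    baseline_offset: float = 0.2,
    noise: float = 0.005,
    eta: float = 0.15,
) -> Thermogram:
    """Single pseudo-Voigt endotherm on a gentle linear baseline plus seeded
    noise (SD = ``noise`` x peak height).  Tm/dH/fwhm come from the effect
    model; ground truth is stored in the metadata."""
    tm = em.level(membrane, "Tm", conc)
    dh = em.level(membrane, "dH", conc)
    fwhm = em.level(membrane, "fwhm", conc)
    T = np.arange(T_lo, T_hi + 0.5 * dT, dT)
    peak = pseudo_voigt(T, tm, fwhm, dh, eta=eta)
    base = baseline_offset + baseline_slope * (T - T_lo)
    rng = np.random.default_rng(seed)
    cp = peak + base + noise * peak.max() * rng.standard_normal(len(T))
    return Thermogram(
        T=T,
        cp_excess=cp,
        scan_rate=5.0,
        direction="heating",
        meta={
            "Tm_true": tm, "dH_true": dh, "fwhm_true": fwhm,
            "membrane": membrane, "serotonin_mM": conc, "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# Raman spectra


def _gauss(x: np.ndarray, center: float, fwhm: float, height: float) -> np.ndarray:
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return height * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def gen_serotonin_reference(
    grid: np.ndarray | None = None, fwhm: float = 14.0
) -> RamanSpectrum:
    """Synthetic serotonin reference spectrum: the ~1540 cm^-1 indole
    ring-stretching band plus aromatic/aliphatic C-H contributions in the
    2800-3000 cm^-1 window."""
    if grid is None:
        grid = np.arange(1400.0, 3100.0, 0.5)
    y = (
        _gauss(grid, 1540.0, fwhm, 1.0)
        + _gauss(grid, 2900.0, 22.0, 0.55)
        + _gauss(grid, 2960.0, 20.0, 0.35)
    )
    return RamanSpectrum(wavenumber=grid, intensity=y, label="serotonin_reference")


def gen_raman_spectrum(
    em: EffectModel,
    membrane: str = "DOPC",
    conc: float = 0.0,
    seed: int = 0,
    band_fwhm: float = 12.0,
    baseline_slope: float = 1e-4,
    baseline_offset: float = 0.05,
    noise: float = 0.002,
    serotonin_weight_max: float = 0.5,
) -> tuple[RamanSpectrum, RamanSpectrum]:
    """Synthetic sample spectrum and the matching serotonin reference.

    The lipid contribution has Gaussian bands at 2850/2890/2930 cm^-1 whose
    heights are driven by the effect model so that I2930/I2890 rises with
    dose; a dose-scaled serotonin spectrum (with its 1540 cm^-1 marker band)
    is added on top, then a linear baseline and seeded noise.  Ground-truth
    band heights and ratios are recorded in the metadata.
    """
    grid = np.arange(1400.0, 3100.0, 0.5)
    f = em.dose_factor(conc)
    target_r = em.level(membrane, "ratio", conc)
    h2850 = 1.0
    h2890 = 0.8 * (1.0 - 0.25 * f)  # antisymmetric band weakens with disorder
    h2930 = h2890 * target_r
    lipid = (
        _gauss(grid, 2850.0, band_fwhm, h2850)
        + _gauss(grid, 2890.0, band_fwhm, h2890)
        + _gauss(grid, 2930.0, band_fwhm, h2930)
    )
    ref = gen_serotonin_reference(grid)
    w = serotonin_weight_max * f
    rng = np.random.default_rng(seed)
    y = (
        lipid
        + w * ref.intensity
        + baseline_offset
        + baseline_slope * (grid - grid[0])
        + noise * rng.standard_normal(len(grid))
    )
    sample = RamanSpectrum(
        wavenumber=grid,
        intensity=y,
        label=f"{membrane}:{conc}mM",
        meta={
            "membrane": membrane, "serotonin_mM": conc, "seed": seed,
            "h2850": h2850, "h2890": h2890, "h2930": h2930,
            "ratio_true": target_r, "serotonin_weight": w,
            "rel_ratio_true": target_r / em.level(membrane, "ratio", 0.0),
        },
    )
    return sample, ref


# ---------------------------------------------------------------------------
# study tables and images


def gen_study_dataset(
    em: EffectModel,
    n_replicates: int = 3,
    seed: int = 0,
    observables: tuple[str, ...] = OBSERVABLES,
    membranes: tuple[str, ...] = MEMBRANES,
    concentrations: tuple[float, ...] = CONCENTRATIONS,
) -> dict[str, StudyTable]:
    """Replicated factorial tables (membrane x concentration) for each
    observable, sampled around the effect-model levels with the per-
    observable noise SDs (relative, except Tm which is additive in C)."""
    rng = np.random.default_rng(seed)
    out: dict[str, StudyTable] = {}
    for obs in observables:
        rows = []
        for mem in membranes:
            for conc in concentrations:
                mu = em.level(mem, obs, conc)
                sd = em.noise_sd[obs]
                for rep in range(n_replicates):
                    if obs == "Tm":
                        val = mu + sd * rng.standard_normal()
                    else:
                        val = mu * (1.0 + sd * rng.standard_normal())
                    rows.append(
                        {"membrane": mem, "conc": conc, "replicate": rep, "value": val}
                    )
        import pandas as pd

        out[obs] = StudyTable(data=pd.DataFrame(rows), units=obs)
    return out


def gen_droplet_image(
    geom: DropletPairGeometry | tuple[Circle, Circle],
    shape: tuple[int, int] = (200, 300),
    noise: float = 0.0,
    seed: int = 0,
    foreground: float = 1.0,
    background: float = 0.0,
) -> tuple[np.ndarray, tuple[Circle, Circle]]:
    """Render a droplet pair as two bright antialiased disks (union) on a
    dark background, with optional additive Gaussian noise (SD = ``noise`` x
    dynamic range).  Returns the image and the ground-truth circles.

    A :class:`DropletPairGeometry` is centered in the frame with the pair
    axis horizontal; alternatively two explicit circles (in px) are drawn.
    """
    h, w = shape
    if isinstance(geom, DropletPairGeometry):
        cy = h / 2.0
        cx1 = w / 2.0 - geom.D / 2.0
        cx2 = w / 2.0 + geom.D / 2.0
        c1 = Circle(cx=cx1, cy=cy, r=geom.R1)
        c2 = Circle(cx=cx2, cy=cy, r=geom.R2)
    else:
        c1, c2 = geom
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full((h, w), float(background))
    for c in (c1, c2):
        dist = np.hypot(xx - c.cx, yy - c.cy)
        disk = np.clip(c.r - dist + 0.5, 0.0, 1.0)  # 1-px antialiased edge
        img = np.maximum(img, background + (foreground - background) * disk)
    if noise > 0:
        rng = np.random.default_rng(seed)
        img = img + noise * (foreground - background) * rng.standard_normal(img.shape)
    return img, (c1, c2)
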