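"""DSC thermogram reduction.

A differential scanning calorimetry heating scan of a lipid lamellar phase
shows a single endothermic main transition (gel L_beta to liquid-crystalline
L_alpha).  The reduction pipeline is: subtract an instrumental baseline
interpolated between the flat pre- and post-transition flanks, then read off

* Tm    — temperature at the peak of the excess heat capacity (parabolic
          refinement over the three points around the maximum),
* dH    — transition enthalpy, trapezoidal integral of the corrected trace
          over the peak support,
* fwhm  — full width at half the peak height, by linear interpolation of
          the half-height crossings.

The baseline is by default a sigmoidal interpolation between linear fits to
the two flanks, weighted by the cumulative peak area (so the step tracks the
progress of the transition); a plain linear baseline is available via
``baseline="linear"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class NoTransitionError(ValueError):
    """No peak above the noise threshold, or the peak is unusable."""


@dataclass
class Thermogram:
    """A heat-capacity trace: temperature grid T (C, increasing) and molar
    excess heat capacity cp_excess (kcal mol^-1 C^-1)."""

    T: np.ndarray
    cp_excess: np.ndarray
    scan_rate: float = 5.0  # C/min
    direction: str = "heating"
    lipid_mol: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.cp_excess = np.asarray(self.cp_excess, dtype=float)
        if self.T.ndim != 1 or self.T.shape != self.cp_excess.shape:
            raise ValueError("T and cp_excess must be 1-D arrays of equal length")
        if np.any(np.diff(self.T) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if not np.all(np.isfinite(self.cp_excess)):
            raise ValueError("cp_excess must be finite")
        if self.direction not in ("heating", "cooling"):
            raise ValueError("direction must be 'heating' or 'cooling'")


@dataclass
class TransitionSummary:
    """Reduced main-transition parameters: Tm (C), dH (kcal/mol), fwhm (C),
    and optionally the control-relative dTm = Tm - Tm0 and rel_dH = dH/dH0."""

    Tm: float
    dH: float
    fwhm: float
    dTm: float | None = None
    rel_dH: float | None = None


def _flank_slices(n: int, flank_frac: float) -> tuple[slice, slice]:
    k = max(3, int(round(flank_frac * n)))
    return slice(0, k), slice(n - k, n)


def _fitted_baseline(T: np.ndarray, cp: np.ndarray) -> np.ndarray:
    """Linear baseline from a joint least-squares fit of (pseudo-Voigt peak
    + a + b*T); only the baseline part is returned.

    Interpolated flank baselines absorb the peak's tails (the flank fit sits
    on top of them), clipping a few percent of the enthalpy of broad or
    tailed transitions; the joint fit separates peak from baseline instead.
    """
    from scipy.ndimage import uniform_filter1d
    from scipy.optimize import least_squares

    n = len(T)
    left, right = _flank_slices(n, 0.15)
    pl = np.polyfit(np.concatenate([T[left], T[right]]),
                    np.concatenate([cp[left], cp[right]]), 1)
    rough = uniform_filter1d(cp - np.polyval(pl, T), size=max(5, n // 100))
    ipk = int(np.argmax(rough))
    h0 = max(rough[ipk], 1e-12)
    above = np.flatnonzero(rough > 0.5 * h0)
    w0 = max(float(T[above[-1]] - T[above[0]]), 4 * (T[1] - T[0]))

    def model(p):
        h, x0, w, eta, a, b = p
        prof = pseudo_voigt_profile(T, x0, w, eta)
        return h * prof + a + b * T

    p0 = [h0, float(T[ipk]), w0, 0.3, pl[1], pl[0]]
    span = float(T[-1] - T[0])
    sol = least_squares(
        lambda p: model(p) - cp,
        p0,
        bounds=(
            [0.0, T[0], 1e-3 * span, 0.0, -np.inf, -np.inf],
            [np.inf, T[-1], 2.0 * span, 1.0, np.inf, np.inf],
        ),
        xtol=1e-12,
        ftol=1e-12,
    )
    _, _, _, _, a, b = sol.x
    return a + b * T


def pseudo_voigt_profile(x: np.ndarray, center: float, fwhm: float,
                         eta: float) -> np.ndarray:
    """Unit-height pseudo-Voigt: eta * Lorentzian + (1 - eta) * Gaussian,
    both with the same fwhm."""
    hwhm = fwhm / 2.0
    lor = hwhm**2 / ((x - center) ** 2 + hwhm**2)
    gau = np.exp(-np.log(2.0) * ((x - center) / hwhm) ** 2)
    return eta * lor + (1.0 - eta) * gau


def baseline_correct(
    tg: Thermogram,
    flank_frac: float = 0.15,
    baseline: str = "fitted",
    n_iter: int = 4,
) -> Thermogram:
    """Subtract the instrumental baseline from a thermogram.

    ``baseline="fitted"`` (default) jointly fits a pseudo-Voigt transition
    plus a linear baseline and subtracts only the baseline part, so that
    peak tails are not clipped into the baseline.  The flank-interpolation
    alternatives fit linear segments to the first and last ``flank_frac``
    of the scan window: ``"sigmoid"`` steps between them weighted by the
    cumulative peak area (the baseline shifts with the fraction of lipid
    converted), ``"linear"`` interpolates the segments linearly in T.
    """
    T, cp = tg.T, tg.cp_excess
    sign = 1.0 if tg.direction == "heating" else -1.0
    cp = sign * cp
    n = len(T)
    if n < 20:
        raise ValueError("thermogram too short to identify flanks")
    left, right = _flank_slices(n, flank_frac)

    if baseline == "fitted":
        base = _fitted_baseline(T, cp)
    elif baseline in ("linear", "sigmoid"):
        pl = np.polyfit(T[left], cp[left], 1)
        pr = np.polyfit(T[right], cp[right], 1)
        bl = np.polyval(pl, T)
        br = np.polyval(pr, T)
        if baseline == "linear":
            w = (T - T[left].mean()) / (T[right].mean() - T[left].mean())
            w = np.clip(w, 0.0, 1.0)
            base = (1 - w) * bl + w * br
        else:
            base = 0.5 * (bl + br)
            for _ in range(n_iter):
                excess = np.clip(cp - base, 0.0, None)
                cum = np.concatenate([[0.0], np.cumsum(
                    0.5 * (excess[1:] + excess[:-1]) * np.diff(T)
                )])
                total = cum[-1]
                w = cum / total if total > 0 else np.linspace(0, 1, n)
                base = (1 - w) * bl + w * br
    else:
        raise ValueError(f"unknown baseline model {baseline!r}")

    corrected = cp - base
    # flanks must be flat after correction, else the window was unsuitable
    peak = float(np.max(np.abs(corrected)))
    if peak > 0:
        for sl in (left, right):
            if np.mean(np.abs(corrected[sl])) > 0.25 * peak:
                raise NoTransitionError(
                    "no identifiable flat flank: transition spans the scan window"
                )
    return replace(tg, cp_excess=corrected, direction="heating")


def _parabolic_refine(T: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through points i-1, i, i+1; falls back to the
    grid point at window edges."""
    if i == 0 or i == len(T) - 1:
        return float(T[i]), float(y[i])
    x = T[i - 1 : i + 2]
    z = y[i - 1 : i + 2]
    denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
    a = (x[2] * (z[1] - z[0]) + x[1] * (z[0] - z[2]) + x[0] * (z[2] - z[1])) / denom
    b = (
        x[2] ** 2 * (z[0] - z[1])
        + x[1] ** 2 * (z[2] - z[0])
        + x[0] ** 2 * (z[1] - z[2])
    ) / denom
    if a >= 0:
        return float(T[i]), float(y[i])
    xv = -b / (2 * a)
    c = z[0] - a * x[0] ** 2 - b * x[0]
    return float(xv), float(a * xv**2 + b * xv + c)


def _half_crossings(T: np.ndarray, y: np.ndarray, half: float, ipk: int) -> float:
    left = None
    for j in range(ipk, 0, -1):
        if y[j - 1] <= half <= y[j]:
            f = (half - y[j - 1]) / (y[j] - y[j - 1])
            left = T[j - 1] + f * (T[j] - T[j - 1])
            break
    right = None
    for j in range(ipk, len(T) - 1):
        if y[j + 1] <= half <= y[j]:
            f = (y[j] - half) / (y[j] - y[j + 1])
            right = T[j] + f * (T[j + 1] - T[j])
            break
    if left is None or right is None:
        raise NoTransitionError("half-height crossings outside the scan window")
    return float(right - left)


def _smoothed(cp: np.ndarray, T: np.ndarray, fwhm_rough: float) -> np.ndarray:
    """Savitzky-Golay (order 2) smoothing with a window of ~fwhm/3; order-2
    SG leaves the quadratic peak top unbiased while averaging out noise."""
    from scipy.signal import savgol_filter

    dT = float(np.median(np.diff(T)))
    w = int(round(fwhm_rough / (3.0 * dT)))
    w = max(5, w) | 1  # odd, at least 5 points
    if w >= len(cp):
        w = (len(cp) - 1) | 1
    return savgol_filter(cp, w, 2)


def analyze_transition(
    tg: Thermogram,
    flank_frac: float = 0.15,
    support_frac: float = 0.01,
    noise_sigma_mult: float = 5.0,
) -> TransitionSummary:
    """Reduce a baseline-corrected thermogram to (Tm, dH, fwhm).

    The peak must exceed ``noise_sigma_mult`` times the flank standard
    deviation, else :class:`NoTransitionError` is raised.  Peak location,
    half-height crossings and the integration support are read off a
    lightly smoothed trace (so replicate noise cannot spoof crossings); dH
    integrates the raw corrected trace over the contiguous region around
    the peak where the smoothed trace exceeds ``support_frac`` of the peak
    height, extended outward to its nearest zero crossings.
    """
    T, cp = tg.T, tg.cp_excess
    n = len(T)
    left, right = _flank_slices(n, flank_frac)
    flank = np.concatenate([cp[left], cp[right]])
    noise = float(np.std(flank))

    ipk0 = int(np.argmax(cp))
    height0 = float(cp[ipk0])
    if height0 <= 0 or height0 < noise_sigma_mult * noise:
        raise NoTransitionError("no peak above the noise threshold")

    # rough width from a heavily smoothed pass, then the working smoothing
    from scipy.ndimage import uniform_filter1d

    rough = uniform_filter1d(cp, size=max(5, n // 100))
    irough = int(np.argmax(rough))
    try:
        fwhm_rough = _half_crossings(T, rough, 0.5 * rough[irough], irough)
    except NoTransitionError:
        fwhm_rough = (T[-1] - T[0]) / 10.0
    ys = _smoothed(cp, T, fwhm_rough)

    ipk = int(np.argmax(ys))
    if ipk in (0, n - 1) or ipk < left.stop or ipk >= right.start:
        raise NoTransitionError("peak at the scan-window edge")
    Tm, h_ref = _parabolic_refine(T, ys, ipk)

    # support: smoothed trace above support_frac * height, then out to its
    # nearest zero crossings
    thr = support_frac * h_ref
    lo = ipk
    while lo > 0 and ys[lo - 1] > thr:
        lo -= 1
    while lo > 0 and ys[lo - 1] > 0:
        lo -= 1
    hi = ipk
    while hi < n - 1 and ys[hi + 1] > thr:
        hi += 1
    while hi < n - 1 and ys[hi + 1] > 0:
        hi += 1
    dH = float(np.trapezoid(cp[lo : hi + 1], T[lo : hi + 1]))

    fwhm = _half_crossings(T, ys, 0.5 * h_ref, ipk)
    return TransitionSummary(Tm=Tm, dH=dH, fwhm=fwhm)


def thermo_summary(
    summaries: dict[float, TransitionSummary], control_key: float = 0.0
) -> dict[float, TransitionSummary]:
    """Fill dTm = Tm - Tm0 and rel_dH = dH/dH0 relative to the control entry.

    ``summaries`` is keyed by serotonin dose (mM or molar-ratio equivalent);
    the control must be present under ``control_key``.
    """
    if control_key not in summaries:
        raise ValueError(f"control key {control_key} missing from summaries")
    s0 = summaries[control_key]
    out = {}
    for k, s in summaries.items():
        out[k] = replace(s, dTm=s.Tm - s0.Tm, rel_dH=s.dH / s0.dH if s0.dH else None)
    return out
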