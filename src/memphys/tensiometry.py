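"""Bilayer tension from monolayer tension and contact angle.

For a droplet interface bilayer the mechanical balance at the contact line
relates the bilayer tension to the monolayer tension and contact angle:

    gamma_b = 2 * gamma_m * cos(theta)

with theta in degrees externally (converted internally).  The module also
builds control-normalized tension tables (gamma_b / gamma_b at 0 mM) for
dose-response comparisons across membrane compositions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


class MissingControlError(ValueError):
    """A membrane series lacks its 0 mM control record."""


@dataclass
class TensionRecord:
    """One tensiometry measurement: serotonin concentration (mM), monolayer
    tension gamma_m (mN/m), contact angle theta (degrees), derived bilayer
    tension gamma_b (mN/m) and the membrane label."""

    serotonin_mM: float
    gamma_m: float
    theta: float
    gamma_b: float
    membrane: str = ""
    gamma_b_rel: float | None = None


def bilayer_tension(gamma_m: float, theta: float) -> float:
    """gamma_b = 2 * gamma_m * cos(theta), theta in degrees.

    theta >= 90 means the droplets do not adhere (no bilayer); gamma_m must
    be positive.
    """
    if gamma_m <= 0:
        raise ValueError(f"monolayer tension must be positive, got {gamma_m}")
    if not (0 <= theta < 90):
        raise ValueError(
            f"contact angle {theta} deg outside [0, 90): non-adherent configuration"
        )
    return 2.0 * gamma_m * math.cos(math.radians(theta))


def bilayer_tension_stderr(
    gamma_m: float, theta: float, sd_gamma_m: float, sd_theta_deg: float
) -> float:
    """First-order propagated SD of gamma_b from SDs of gamma_m and theta."""
    th = math.radians(theta)
    sd_th = math.radians(sd_theta_deg)
    return math.hypot(2 * math.cos(th) * sd_gamma_m, 2 * gamma_m * math.sin(th) * sd_th)


def theta_from_tensions(gamma_b: float, gamma_m: float) -> float:
    """Invert the tension balance: theta (degrees) = arccos(gamma_b / 2 gamma_m)."""
    x = gamma_b / (2.0 * gamma_m)
    if not (0 < x <= 1):
        raise ValueError("gamma_b / (2 gamma_m) outside (0, 1]: no valid angle")
    return math.degrees(math.acos(x))


def tension_table(
    records: list[tuple[float, float, float]] | list[tuple[float, float, float, str]],
) -> list[TensionRecord]:
    """Fill gamma_b and control-relative gamma_b for a list of
    (conc_mM, gamma_m, theta[, membrane]) records.

    Each membrane series must contain exactly one conc = 0 control; relative
    values are normalized to that control's gamma_b.
    """
    recs = []
    for rec in records:
        conc, gm, th = rec[:3]
        mem = rec[3] if len(rec) > 3 else ""
        recs.append(
            TensionRecord(
                serotonin_mM=float(conc),
                gamma_m=float(gm),
                theta=float(th),
                gamma_b=bilayer_tension(gm, th),
                membrane=mem,
            )
        )
    for mem in {r.membrane for r in recs}:
        series = [r for r in recs if r.membrane == mem]
        controls = [r for r in series if r.serotonin_mM == 0]
        if len(controls) != 1:
            raise MissingControlError(
                f"membrane {mem!r}: expected exactly one 0 mM control, "
                f"found {len(controls)}"
            )
        gb0 = controls[0].gamma_b
        for r in series:
            r.gamma_b_rel = r.gamma_b / gb0
    return recs


def tension_frame(records) -> pd.DataFrame:
    """Tidy DataFrame of :func:`tension_table` output, gamma_b rounded to the
    2 decimals used in report tables."""
    recs = tension_table(records)
    return pd.DataFrame(
        {
            "membrane": [r.membrane for r in recs],
            "serotonin_mM": [r.serotonin_mM for r in recs],
            "gamma_m_mN_m": [r.gamma_m for r in recs],
            "theta_deg": [r.theta for r in recs],
            "gamma_b_mN_m": [round(r.gamma_b, 2) for r in recs],
            "gamma_b_rel": [r.gamma_b_rel for r in recs],
        }
    )


def tension_frame_from_csv(path) -> pd.DataFrame:
    """Read a tensiometry CSV (columns serotonin_mM, gamma_m_mN_m, theta_deg,
    optional membrane) and return the filled tension table."""
    df = pd.read_csv(path)
    required = {"serotonin_mM", "gamma_m_mN_m", "theta_deg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    mems = df["membrane"] if "membrane" in df.columns else [""] * len(df)
    records = list(
        zip(df["serotonin_mM"], df["gamma_m_mN_m"], df["theta_deg"], mems)
    )
    return tension_frame(records)
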