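"""Bundled reference measurements used in examples and worked analyses.

Small printed tables from the serotonin-membrane study this toolkit was
built around: tensiometry of DOPC and DOPC/SM/Chol (1:1:0.2) bilayers at
25 C as a function of serotonin HCl concentration, and the control water
permeabilities of the three droplet-interface-bilayer compositions at 30 C.
"""

from __future__ import annotations

import pandas as pd

#: (serotonin mM, monolayer tension mN/m, contact angle deg) per membrane
TENSIOMETRY = {
    "DOPC": [
        (0, 1.125, 31.20),
        (1, 1.082, 29.80),
        (5, 0.982, 30.89),
        (10, 0.931, 33.90),
        (20, 0.864, 40.35),
        (40, 0.664, 48.71),
    ],
    "DOPC/SM/Chol": [
        (0, 1.185, 23.96),
        (1, 1.042, 24.16),
        (5, 0.990, 24.61),
        (10, 0.900, 27.13),
        (20, 0.627, 29.71),
        (40, 0.428, 35.95),
    ],
}

#: bilayer tensions (mN/m) reported alongside the table above
TENSIOMETRY_GAMMA_B = {
    "DOPC": [1.92, 1.88, 1.69, 1.55, 1.32, 0.88],
    "DOPC/SM/Chol": [2.17, 1.90, 1.80, 1.60, 1.09, 0.69],
}

#: control osmotic water permeability coefficients, um/s at 30 C
PF_CONTROLS = {"DOPC": 73.0, "DOPC/DOPS": 62.0, "DOPC/SM/Chol": 67.0}

#: control DSC main-transition parameters: Tm (C), dH (kcal/mol), fwhm (C)
DSC_CONTROLS = {
    "DOPC": (-16.68, 8.34, 1.50),
    "DOPC/DOPS": (-15.88, 9.10, 0.95),
    "DOPC/SM/Chol": (-18.67, 2.67, 2.73),
}


def tensiometry_records() -> list[tuple[float, float, float, str]]:
    """Flat (conc, gamma_m, theta, membrane) records for the tension table."""
    return [
        (c, gm, th, mem)
        for mem, rows in TENSIOMETRY.items()
        for (c, gm, th) in rows
    ]


def tensiometry_frame() -> pd.DataFrame:
    """The tensiometry dataset as a tidy DataFrame."""
    return pd.DataFrame(
        tensiometry_records(),
        columns=["serotonin_mM", "gamma_m_mN_m", "theta_deg", "membrane"],
    )
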