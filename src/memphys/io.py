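"""Tidy CSV/JSON readers and writers for the pipeline's file formats.

Every instrument trace travels as a two-column CSV with a JSON metadata
sidecar next to it (same stem, ``.json`` suffix); result tables are tidy
CSVs.  Droplet time-series I/O lives on
:class:`memphys.osmosis.DropletTimeSeries` itself.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .calorimetry import Thermogram
from .raman import RamanSpectrum


def _sidecar(path: Path) -> dict:
    side = path.with_suffix(".json")
    return json.loads(side.read_text()) if side.exists() else {}


def read_thermogram(path: str | Path) -> Thermogram:
    """Thermogram CSV with columns T_C, cp_kcal_per_mol_C (+ JSON sidecar
    with scan_rate_C_min / direction / lipid_mol)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"T_C", "cp_kcal_per_mol_C"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    meta = _sidecar(path)
    return Thermogram(
        T=df["T_C"].to_numpy(),
        cp_excess=df["cp_kcal_per_mol_C"].to_numpy(),
        scan_rate=meta.pop("scan_rate_C_min", 5.0),
        direction=meta.pop("direction", "heating"),
        lipid_mol=meta.pop("lipid_mol", 1.0),
        meta=meta,
    )


def write_thermogram(tg: Thermogram, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"T_C": tg.T, "cp_kcal_per_mol_C": tg.cp_excess}).to_csv(
        path, index=False
    )
    path.with_suffix(".json").write_text(
        json.dumps(
            {
                "scan_rate_C_min": tg.scan_rate,
                "direction": tg.direction,
                "lipid_mol": tg.lipid_mol,
                **{k: v for k, v in tg.meta.items()},
            },
            indent=2,
            default=float,
        )
    )


def read_spectrum(path: str | Path) -> RamanSpectrum:
    """Raman spectrum CSV with columns wavenumber_cm1, intensity_au."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"wavenumber_cm1", "intensity_au"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    meta = _sidecar(path)
    return RamanSpectrum(
        wavenumber=df["wavenumber_cm1"].to_numpy(),
        intensity=df["intensity_au"].to_numpy(),
        label=meta.pop("label", path.stem),
        meta=meta,
    )


def write_spectrum(s: RamanSpectrum, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {"wavenumber_cm1": s.wavenumber, "intensity_au": s.intensity}
    ).to_csv(path, index=False)
    path.with_suffix(".json").write_text(
        json.dumps({"label": s.label, **s.meta}, indent=2, default=float)
    )
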