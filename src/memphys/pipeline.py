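"""End-to-end analysis chain: per-assay reduction, control normalization,
ANOVA/Tukey annotation, and the run report bundle."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calorimetry, osmosis, raman, stats, synthetic, tensiometry
from .synthetic import CONCENTRATIONS, MEMBRANES, EffectModel


@dataclass
class PipelineConfig:
    """All tunables of the analysis chain in one place.

    Defaults match the study conditions: water molar volume 18.05 cm^3/mol,
    186 mOsm/kg hyperosmotic droplet (0.1 M NaCl), sigmoidal DSC baseline,
    +/-10 cm^-1 Raman band windows, balanced two-way ANOVA.
    """

    input_dir: str | None = None
    out_dir: str = "memphys_results"
    synthetic: bool = True
    seed: int = 0
    n_replicates: int = 3
    Vw_um3_per_mol: float = osmosis.VW_UM3_PER_MOL
    osmolality_mOsm_kg: float = osmosis.DEFAULT_OSMOLALITY_MOSM_KG
    dsc_baseline: str = "sigmoid"
    raman_band_method: str = "max"
    pf_method: str = "ode_fit"
    cap_correction: bool = False  # droplets treated as full spheres
    dynamic_area: bool = False
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def membrane_sensitivity(tbl: stats.StudyTable, conc: float | None = None) -> pd.Series:
    """Per-membrane effect magnitude: |control-normalized mean at the highest
    dose - 1|.  Used to rank membrane models by their sensitivity to
    serotonin."""
    norm = stats.normalize_table(tbl)
    cmax = conc if conc is not None else norm["conc"].max()
    sel = norm[norm["conc"] == cmax].set_index("membrane")["mean_rel"]
    return (sel - 1.0).abs().sort_values(ascending=False)


def analyze_study_tables(
    tables: dict[str, stats.StudyTable], alpha: float = 0.05
) -> dict[str, dict]:
    """Normalize, run the two-way ANOVA and Tukey families for each
    observable's StudyTable."""
    out = {}
    for obs, tbl in tables.items():
        res = stats.two_way_anova(tbl)
        out[obs] = {
            "normalized": stats.normalize_table(tbl),
            "anova": res,
            "tukey_conc": stats.tukey_hsd(
                tbl, "conc-within-membrane", mse=res.mse, df_resid=res.df_resid
            ),
            "tukey_membrane": stats.tukey_hsd(
                tbl, "membrane-within-conc", mse=res.mse, df_resid=res.df_resid
            ),
            "sensitivity": membrane_sensitivity(tbl),
        }
    return out


def _tension_table_from_effect_model(em: EffectModel) -> pd.DataFrame:
    records = [
        (conc, em.level(mem, "gamma_m", conc), em.level(mem, "theta", conc), mem)
        for mem in MEMBRANES
        for conc in CONCENTRATIONS
    ]
    return tensiometry.tension_frame(records)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run the complete analysis chain and write the report bundle.

    With ``config.synthetic`` the study tables come from the seeded
    generators; otherwise tidy CSVs named ``<observable>_study.csv`` are
    read from ``config.input_dir``.  Writes per-assay normalized tables,
    ANOVA tables, Tukey annotations, the bilayer-tension table and a JSON
    run log (seed, config echo and hash) under ``config.out_dir``; the
    bundle is a pure function of config + inputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    em = EffectModel()

    if config.synthetic:
        tables = synthetic.gen_study_dataset(
            em, n_replicates=config.n_replicates, seed=config.seed
        )
    else:
        if config.input_dir is None:
            raise ValueError("input_dir required when synthetic=False")
        tables = {}
        for path in sorted(Path(config.input_dir).glob("*_study.csv")):
            obs = path.stem.removesuffix("_study")
            df = pd.read_csv(path)
            try:
                tables[obs] = stats.StudyTable(data=df, units=obs)
            except ValueError as exc:
                raise ValueError(f"{path}: {exc}") from exc
        if not tables:
            raise FileNotFoundError(
                f"no *_study.csv tables found in {config.input_dir}"
            )

    results = analyze_study_tables(tables, alpha=config.alpha)
    for obs, r in results.items():
        r["normalized"].to_csv(out_dir / f"{obs}_normalized.csv", index=False)
        r["anova"].table.to_csv(out_dir / f"{obs}_anova.csv")
        r["tukey_conc"].to_csv(out_dir / f"{obs}_tukey_conc.csv", index=False)
        r["tukey_membrane"].to_csv(out_dir / f"{obs}_tukey_membrane.csv", index=False)

    tension = _tension_table_from_effect_model(em) if config.synthetic else None
    if (
        not config.synthetic
        and config.input_dir
        and (Path(config.input_dir) / "tensiometry.csv").exists()
    ):
        tension = tensiometry.tension_frame_from_csv(
            Path(config.input_dir) / "tensiometry.csv"
        )
    if tension is not None:
        tension.to_csv(out_dir / "tension_table.csv", index=False)

    log = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "observables": sorted(results),
        "versions": _versions(),
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    return {"tables": tables, "results": results, "tension": tension, "log": log}


def _versions() -> dict:
    import numpy, pandas, scipy

    import memphys

    return {
        "memphys": memphys.__version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
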