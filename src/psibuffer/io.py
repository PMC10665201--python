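"""Tabular and image I/O.

Osmometry data travel as long-format CSV/TSV with columns
``solute, temperature_C, conc, conc_unit, osmolality_mOsm_kg, sem, replicate,
baseline`` (sem and baseline optional); one DilutionSeries per
(solute, temperature, replicate) group.  Images are read with tifffile/imageio
and masks as 0/255 or label images.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .osmo_model import DilutionSeries, OsmoticModelParams

REQUIRED_COLUMNS = {"solute", "temperature_C", "conc", "osmolality_mOsm_kg"}


def read_dilution_series(path: str | Path, solute: str | None = None,
                         temperature_C: float | None = None) -> list[DilutionSeries]:
    """Read every (solute, temperature, replicate) curve from a long-format table."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = REQUIRED_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if solute is not None:
        df = df[df["solute"] == solute]
    if temperature_C is not None:
        df = df[np.isclose(df["temperature_C"], temperature_C)]
    if df.empty:
        raise ValueError(f"{path}: no rows match the requested solute/temperature")
    if "replicate" not in df.columns:
        df = df.assign(replicate="rep0")
    out = []
    for (sol, t, rep), g in df.groupby(["solute", "temperature_C", "replicate"], sort=True):
        g = g.sort_values("conc")
        out.append(
            DilutionSeries(
                solute_name=str(sol),
                temperature=float(t),
                concentrations=g["conc"].to_numpy(),
                osmolality=g["osmolality_mOsm_kg"].to_numpy(),
                conc_unit=str(g["conc_unit"].iloc[0]) if "conc_unit" in g else "mg/ml",
                sem=g["sem"].to_numpy() if "sem" in g and g["sem"].notna().all() else None,
                replicate_id=str(rep),
                baseline_osmolality=float(g["baseline"].iloc[0]) if "baseline" in g else 0.0,
            )
        )
    return out


def write_dilution_series(series: list[DilutionSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for i, c in enumerate(s.concentrations):
            rows.append(
                {
                    "solute": s.solute_name,
                    "temperature_C": round(s.temperature - 273.15, 6),
                    "conc": c,
                    "conc_unit": s.conc_unit,
                    "osmolality_mOsm_kg": s.osmolality[i],
                    "sem": s.sem[i] if s.sem is not None else np.nan,
                    "replicate": s.replicate_id,
                    "baseline": s.baseline_osmolality,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def params_to_json(params: OsmoticModelParams, path: str | Path | None = None) -> str:
    payload = json.dumps(asdict(params), indent=2, default=float)
    if path is not None:
        Path(path).write_text(payload + "\n")
    return payload


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return np.asarray(tifffile.imread(path), dtype=float)
    return np.asarray(iio.imread(path), dtype=float)


def read_mask(path: str | Path) -> np.ndarray:
    return read_image(path) > 0
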