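"""CSV readers and writers for the pipeline's tabular interchange formats.

All formats are plain RFC-4180 CSV:

* ``compounds.csv`` — id, common_name, iupac_name, class, r1, r2, r3, n_oh,
  n_och3, has_catechol
* ``measurements.csv`` (long) — analyte, assay, concentration_um,
  replicate_index, value, units; analyte is a compound id or a '+'-joined
  mixture label
* ``kinetics.csv`` — well, role, time_min, fluorescence
* ``standards.csv`` — analyte, concentration_um, response
"""

from __future__ import annotations

import statistics
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .assays import KineticCurve
from .panel import PhenolicCompound

__all__ = [
    "panel_frame",
    "write_compounds",
    "read_measurements",
    "write_measurements",
    "summarize_measurements",
    "read_kinetics",
    "read_standards",
]

_MEASUREMENT_COLUMNS = ["analyte", "assay", "concentration_um", "replicate_index", "value", "units"]


def panel_frame(panel: Sequence[PhenolicCompound]) -> pd.DataFrame:
    rows = []
    for c in panel:
        subs = c.substituents or {}
        rows.append(
            {
                "id": c.id,
                "common_name": c.common_name,
                "iupac_name": c.iupac_name,
                "class": c.compound_class,
                "r1": subs.get("R1", ""),
                "r2": subs.get("R2", ""),
                "r3": subs.get("R3", ""),
                "n_oh": c.n_oh,
                "n_och3": c.n_och3,
                "has_catechol": c.has_catechol,
            }
        )
    return pd.DataFrame(rows)


def write_compounds(panel: Sequence[PhenolicCompound], path: str | Path) -> None:
    panel_frame(panel).to_csv(path, index=False)


def read_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_MEASUREMENT_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: measurements file missing columns {sorted(missing)}")
    return df


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in _MEASUREMENT_COLUMNS if c in df.columns]
    df.loc[:, cols].to_csv(path, index=False)


def summarize_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate-level rows to (analyte, assay, concentration) summaries."""
    def agg(g: pd.DataFrame) -> pd.Series:
        values = g["value"].tolist()
        return pd.Series(
            {
                "mean": statistics.fmean(values),
                "sd": statistics.stdev(values) if len(values) > 1 else 0.0,
                "n": len(values),
            }
        )

    out = (
        df.groupby(["analyte", "assay", "concentration_um"], sort=False)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out


def read_kinetics(path: str | Path) -> list[KineticCurve]:
    df = pd.read_csv(path)
    missing = {"well", "role", "time_min", "fluorescence"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: kinetics file missing columns {sorted(missing)}")
    curves = []
    for (well, role), g in df.groupby(["well", "role"], sort=False):
        g = g.sort_values("time_min")
        curves.append(
            KineticCurve(
                well=str(well),
                times=tuple(g["time_min"].astype(float)),
                fluorescence=tuple(g["fluorescence"].astype(float)),
                role=str(role),
            )
        )
    return curves


def write_kinetics(curves: Iterable[KineticCurve], path: str | Path) -> None:
    rows = [
        {"well": c.well, "role": c.role, "time_min": t, "fluorescence": f}
        for c in curves
        for t, f in zip(c.times, c.fluorescence)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_standards(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"concentration_um", "response"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: standards file missing columns {sorted(missing)}")
    return df
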