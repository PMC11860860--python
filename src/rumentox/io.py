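"""CSV/JSON glue: one tidy dialect everywhere (comma, '.' decimal, UTF-8).

Concentration tables use the header ``run,fermenter,variant,medium,time_h,
analyte,value,unit,censored``; metabolite tables drop the medium/unit/
censored columns; gas curves use ``run,fermenter,variant,time_h,
cum_pressure_psi`` preceded by ``#``-prefixed metadata lines for headspace,
temperature and substrate dry matter.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .datatypes import (
    CONCENTRATION_COLUMNS,
    METABOLITE_COLUMNS,
    FitResult,
    GasCurve,
    normalize_unit,
    validate_concentration_frame,
    validate_metabolite_frame,
)

__all__ = [
    "read_concentration_csv",
    "write_concentration_csv",
    "read_metabolite_csv",
    "write_metabolite_csv",
    "read_gas_csv",
    "write_gas_csv",
    "write_fit_report",
    "convert_units",
]


def read_concentration_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype={"run": str, "fermenter": str})
    except Exception as exc:  # surface file and reason, keep traceback
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    return validate_concentration_frame(df)


def write_concentration_csv(df: pd.DataFrame, path) -> None:
    validate_concentration_frame(df)[CONCENTRATION_COLUMNS].to_csv(path, index=False)


def read_metabolite_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"run": str, "fermenter": str})
    return validate_metabolite_frame(df)


def write_metabolite_csv(df: pd.DataFrame, path) -> None:
    validate_metabolite_frame(df)[METABOLITE_COLUMNS].to_csv(path, index=False)


def write_gas_csv(curves: list[GasCurve], path) -> None:
    """All curves of one context share the metadata header; times rendered
    to 6 decimals so the 5-minute (1/12 h) grid round-trips exactly."""
    if not curves:
        raise ValueError("no curves to write")
    first = curves[0]
    lines = [
        f"# headspace_ml={first.headspace_ml}",
        f"# temp_c={first.temp_c}",
        "run,fermenter,variant,substrate_dm_g,time_h,cum_pressure_psi",
    ]
    for c in curves:
        for t, v in zip(c.times, c.values):
            lines.append(f"{c.run},{c.fermenter},{c.variant},{c.substrate_dm_g},{t:.6f},{float(v)!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_gas_csv(path) -> list[GasCurve]:
    meta = {}
    rows = []
    header = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = float(val)
                continue
            parts = line.split(",")
            if header is None:
                header = parts
                continue
            if len(parts) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}")
            rows.append(dict(zip(header, parts)))
    df = pd.DataFrame(rows)
    curves = []
    for (run, ferm, variant, dm), grp in df.groupby(
        ["run", "fermenter", "variant", "substrate_dm_g"], sort=False
    ):
        curves.append(
            GasCurve(
                run=run, fermenter=ferm, variant=variant,
                times=grp["time_h"].astype(float).to_numpy(),
                values=grp["cum_pressure_psi"].astype(float).to_numpy(),
                value_unit="psi",
                headspace_ml=meta.get("headspace_ml", 106.0),
                temp_c=meta.get("temp_c", 39.0),
                substrate_dm_g=float(dm),
            )
        )
    return curves


def write_fit_report(result: FitResult, path) -> None:
    Path(path).write_text(result.to_json(indent=2) + "\n", encoding="utf-8")


def convert_units(series: pd.DataFrame, target_unit: str) -> pd.DataFrame:
    """Convert a concentration table between ng/mL and ug/mL (factor 1000).

    Censoring limits stored in ``value`` convert identically; the round trip
    is exact up to floating multiplication.
    """
    target = normalize_unit(target_unit)
    df = validate_concentration_frame(series)
    factors = {("ng/mL", "ug/mL"): 1e-3, ("ug/mL", "ng/mL"): 1e3}
    out = df.copy()
    src = df["unit"].iloc[0] if len(df) else target
    if len(df) and src != target:
        out["value"] = out["value"] * factors[(src, target)]
        out["unit"] = target
    return out


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
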