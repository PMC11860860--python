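"""Domain containers shared across the kinetics, gas and fermentation modules.

Concentration and metabolite records travel as tidy :class:`pandas.DataFrame`
objects with fixed column schemas; the small parameter bundles below are
plain dataclasses with eager validation so that invalid kinetic states never
reach an optimizer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

#: canonical unit tags for toxin concentrations
CONCENTRATION_UNITS = ("ng/mL", "ug/mL")

#: aliases accepted on input and normalised to the canonical tag
_UNIT_ALIASES = {"µg/mL": "ug/mL", "ug/ml": "ug/mL", "ng/ml": "ng/mL"}

#: tidy schema for toxin concentration tables
CONCENTRATION_COLUMNS = [
    "run", "fermenter", "variant", "medium", "time_h",
    "analyte", "value", "unit", "censored",
]

#: tidy schema for microbial-metabolite tables (value units depend on analyte)
METABOLITE_COLUMNS = ["run", "fermenter", "variant", "time_h", "analyte", "value"]

#: tidy tables are plain DataFrames validated against the schemas above
ConcentrationSeries = pd.DataFrame
MetaboliteTable = pd.DataFrame

VARIANTS = ("CSM", "PCM", "SMS")
MEDIA = ("vital", "autoclaved")
TOXIN_ANALYTES = ("HGA", "HGB", "MCPrG")


def normalize_unit(unit: str) -> str:
    u = _UNIT_ALIASES.get(unit, unit)
    if u not in CONCENTRATION_UNITS:
        raise ValueError(f"unknown concentration unit {unit!r}; expected one of {CONCENTRATION_UNITS}")
    return u


@dataclass(frozen=True)
class ToxinKineticParams:
    """State of the precursor-product conversion model.

    The precursor (hypoglycin B) is hydrolysed to the product (hypoglycin A)
    with first-order rate constant ``k`` (1/h); the product is cleared with
    first-order rate constant ``l`` (1/h).  Concentrations carry a uniform
    unit tag.
    """

    hga0: float
    hgb0: float
    k: float
    l: float
    unit: str = "ug/mL"

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit", normalize_unit(self.unit))
        if not (self.k > 0):
            raise ValueError(f"conversion rate k must be > 0, got {self.k}")
        if self.l < 0:
            raise ValueError(f"clearance rate l must be >= 0, got {self.l}")
        if self.hga0 < 0 or self.hgb0 < 0:
            raise ValueError("initial concentrations must be non-negative")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GompertzParams:
    """Interpretable gas-kinetics triple.

    ``a`` is the asymptotic gas production (mL/g dry matter), ``b`` the time
    (h) at which one third of ``a`` has been produced, and ``c`` the
    additional time (h) after ``b`` at which 70 % of ``a`` has been produced.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError(f"Gompertz parameters must be positive, got {(self.a, self.b, self.c)}")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class FitResult:
    """Outcome of a nonlinear least-squares fit.

    ``ci95`` maps each parameter name to a ``(lower, upper)`` Wald interval.
    A fit that failed to converge (or whose design is unidentifiable) has
    ``converged=False`` and a diagnostic ``message``; estimates may then be
    missing or meaningless and downstream code must check the flag.
    """

    estimates: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    rmse: float
    r2: float
    converged: bool
    n_obs: int
    mode: str = "individual"
    message: str = ""

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ci95.items():
            est = self.estimates.get(name)
            if est is not None and np.isfinite(lo) and np.isfinite(hi):
                if not (lo <= est <= hi):
                    raise ValueError(f"ci95 for {name} does not bracket the estimate")

    def to_json(self, **kwargs) -> str:
        payload = {
            "parameters": self.estimates,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "rmse": self.rmse,
            "r2": self.r2,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "mode": self.mode,
            "message": self.message,
        }
        kwargs.setdefault("sort_keys", True)
        return json.dumps(payload, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "FitResult":
        d = json.loads(text)
        return cls(
            estimates=d["parameters"],
            ci95={k: tuple(v) for k, v in d["ci95"].items()},
            rmse=d["rmse"], r2=d["r2"], converged=d["converged"],
            n_obs=d["n_obs"], mode=d.get("mode", "individual"),
            message=d.get("message", ""),
        )


@dataclass
class DecayFit:
    """Single-exponential decay fit with its half-life."""

    c0: float
    k: float
    half_life: float
    fit: FitResult

    def __post_init__(self) -> None:
        if self.fit.converged:
            if not self.k > 0:
                raise ValueError("a valid decay fit requires k > 0")
            if not math.isclose(self.half_life, math.log(2) / self.k, rel_tol=1e-12):
                raise ValueError("half_life must equal ln(2)/k")


@dataclass
class GasCurve:
    """Cumulative gas pressure (or volume) time series for one fermenter.

    ``values`` are cumulative and expressed in ``value_unit`` (``psi`` for raw
    recordings, ``mL`` or ``mL/g`` after conversion).  The headspace volume
    and incubation temperature provide the ideal-gas context for the
    pressure-to-volume conversion; ``substrate_dm`` (g dry matter) supports
    per-gram normalisation.
    """

    run: str
    fermenter: str
    variant: str
    times: np.ndarray
    values: np.ndarray
    value_unit: str = "psi"
    headspace_ml: float = 106.0
    temp_c: float = 39.0
    substrate_dm_g: float = 0.2

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size == 0:
            raise ValueError("empty gas curve")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.headspace_ml <= 0:
            raise ValueError("headspace volume must be positive")

    def replace(self, **changes) -> "GasCurve":
        d = {
            "run": self.run, "fermenter": self.fermenter, "variant": self.variant,
            "times": self.times, "values": self.values, "value_unit": self.value_unit,
            "headspace_ml": self.headspace_ml, "temp_c": self.temp_c,
            "substrate_dm_g": self.substrate_dm_g,
        }
        d.update(changes)
        return GasCurve(**d)


def validate_concentration_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a tidy concentration table against the shared schema.

    Enforces column presence, non-negative times and values, known unit tags,
    and uniqueness of (fermenter, time, analyte) within each run/medium.
    Returns the frame with units normalised.
    """
    missing = [c for c in CONCENTRATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"concentration table is missing columns {missing}")
    df = df.copy()
    df["unit"] = df["unit"].map(normalize_unit)
    if df["unit"].nunique() > 1:
        raise ValueError("mixed concentration units in one table; convert first")
    if (df["time_h"] < 0).any():
        raise ValueError("negative sampling times")
    if (df["value"] < 0).any():
        raise ValueError("negative concentrations")
    key = ["run", "medium", "fermenter", "time_h", "analyte"]
    if df.duplicated(subset=key).any():
        dup = df[df.duplicated(subset=key, keep=False)].iloc[0]
        raise ValueError(
            f"duplicate record for fermenter={dup['fermenter']} "
            f"time={dup['time_h']} analyte={dup['analyte']}"
        )
    df["censored"] = df["censored"].astype(bool)
    return df


def validate_metabolite_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METABOLITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metabolite table is missing columns {missing}")
    key = ["run", "fermenter", "time_h", "analyte"]
    if df.duplicated(subset=key).any():
        raise ValueError("duplicate (fermenter, time, analyte) metabolite record")
    return df.copy()
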