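"""Synthetic batch-culture experiments emulating the in vitro study design.

The generator reproduces the layout of the source experiment: four
consecutive runs, each variant (CSM control, PCM spiked pure-toxin mixture,
SMS milled sycamore seeds) incubated in duplicate, destructive sampling at
0/1/2/4/8/24/48 h, four blank fermenters per run, plus autoclaved-medium
controls sampled at 0 and 48 h.  Three linked outputs are produced:

* toxin concentration series — SMS trajectories from the conversion-
  clearance model, PCM from single-exponential decay, with multiplicative
  lognormal measurement noise and left-censoring at the quantification limit;
* cumulative gas-pressure curves at the 5-minute native interval, built by
  inverting the ideal-gas volume conversion on per-variant Gompertz truths,
  on top of a low-level blank background drift;
* metabolite profiles (pH, redox, SCFA, NH3) interpolating the variant's
  0 h and 48 h anchor values along the variant's normalised gas-production
  shape, with additive Gaussian noise.

Every fermenter draws from its own seeded random stream, so subsetting runs
or variants never shifts the draws of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .datatypes import GasCurve, GompertzParams, ToxinKineticParams
from .gas import gompertz_value, volume_to_pressure
from .kinetics import hga_at, hgb_at

__all__ = [
    "ExperimentConfig",
    "SyntheticDataset",
    "generate_toxin_experiment",
    "generate_gas_curves",
    "generate_metabolite_profiles",
    "generate_dataset",
]

LN2 = math.log(2.0)

# -- default truths ---------------------------------------------------------
# Initial toxin concentrations and dispersions follow the measured 0 h values
# (SMS: 4.7 +/- 1.4 ug/mL HGA, 19.9 +/- 5.41 ug/mL HGB, 1.2 +/- 0.33 ug/mL
# MCPrG; PCM: 564 +/- 133 ng/mL HGA, 432 +/- 85.1 ng/mL MCPrG).  PCM decay
# constants derive from the reported half-lives (HGA 2.05 h, MCPrG 2.20 h).
# The SMS conversion rates (k = 0.10/h, l = 0.036/h) are chosen so the model
# peaks near 13.7 h and leaves ~6 ug/mL HGA at 48 h, matching the observed
# trajectory; no rate constants are reported directly.  The SMS MCPrG decay
# connects the measured 0 h (1.2) and 48 h (0.32) means.

DEFAULT_CONVERSION_TRUTH = {
    "SMS": {"hga0": 4.7, "hgb0": 19.9, "k": 0.10, "l": 0.036, "unit": "ug/mL"},
}

DEFAULT_DECAY_TRUTH = {
    "PCM": {
        "HGA": {"c0": 564.0, "k": LN2 / 2.05, "unit": "ng/mL"},
        "MCPrG": {"c0": 432.0, "k": LN2 / 2.20, "unit": "ng/mL"},
    },
    "SMS": {
        "MCPrG": {"c0": 1.2, "k": math.log(1.2 / 0.32) / 48.0, "unit": "ug/mL"},
    },
}

#: coefficient of variation per variant/analyte, from the 0 h SD/mean ratios
DEFAULT_TOXIN_CV = {
    "SMS": {"HGA": 1.4 / 4.7, "HGB": 5.41 / 19.9, "MCPrG": 0.33 / 1.2},
    "PCM": {"HGA": 133.0 / 564.0, "MCPrG": 85.1 / 432.0},
}

#: per-variant Gompertz truth (a mL/g DM, b h, c h)
DEFAULT_GAS_TRUTH = {
    "CSM": (200.0, 18.6, 8.5),
    "PCM": (272.0, 17.5, 10.7),
    "SMS": (453.0, 43.5, 32.1),
}

#: substrate dry matter per fermenter (g); SMS adds 100 mg seeds to 200 mg CSM
DEFAULT_SUBSTRATE_DM = {"CSM": 0.2, "PCM": 0.2, "SMS": 0.3}

#: metabolite anchors: analyte -> variant -> (value at 0 h, value at 48 h, SD)
DEFAULT_METABOLITE_ANCHORS = {
    "pH": {"CSM": (7.0, 6.8, 0.14), "PCM": (6.9, 6.6, 0.024), "SMS": (6.9, 6.7, 0.051)},
    "redox": {"CSM": (-178.0, -215.0, 34.2), "PCM": (-189.0, -249.0, 22.5), "SMS": (-184.0, -280.0, 16.6)},
    "acetic": {"CSM": (18.0, 41.0, 8.5), "PCM": (22.0, 48.0, 1.2), "SMS": (22.0, 64.0, 2.8)},
    "propionic": {"CSM": (6.8, 22.0, 2.7), "PCM": (4.3, 24.0, 0.88), "SMS": (4.5, 11.0, 0.61)},
    "n-butyric": {"CSM": (1.7, 4.5, 1.1), "PCM": (2.1, 4.9, 0.50), "SMS": (2.9, 6.3, 0.55)},
    "iso-butyric": {"CSM": (0.42, 0.75, 0.18), "PCM": (0.20, 0.60, 0.046), "SMS": (0.21, 0.10, 0.013)},
    "n-valeric": {"CSM": (0.14, 0.35, 0.061), "PCM": (0.14, 0.38, 0.023), "SMS": (0.15, 0.39, 0.030)},
    "iso-valeric": {"CSM": (0.58, 1.1, 0.23), "PCM": (0.30, 0.91, 0.069), "SMS": (0.32, 0.14, 0.017)},
    "NH3": {"CSM": (-1.2, -5.7, 1.2), "PCM": (-1.8, -5.3, 0.41), "SMS": (-1.3, -4.8, 0.39)},
}

#: blank NH3 background (mmol/L): inoculum level rising slowly over 48 h
BLANK_NH3_0 = 11.0
BLANK_NH3_48 = 17.0


class ExperimentConfig(BaseModel):
    """Full description of one synthetic batch-culture experiment.

    The defaults reproduce the source study design; every field can be
    overridden, and a (config, seed) pair fully determines the output.
    """

    model_config = ConfigDict(extra="forbid")

    n_runs: int = 4
    n_duplicates: int = 2
    sampling_grid: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0, 24.0, 48.0)
    autoclaved_grid: tuple[float, ...] = (0.0, 48.0)
    variants: tuple[str, ...] = ("CSM", "PCM", "SMS")
    include_autoclaved: bool = True
    autoclaved_attenuation: float = Field(0.25, ge=0)

    conversion_truth: dict = Field(default_factory=lambda: dict(DEFAULT_CONVERSION_TRUTH))
    decay_truth: dict = Field(default_factory=lambda: {v: dict(d) for v, d in DEFAULT_DECAY_TRUTH.items()})
    toxin_cv: dict = Field(default_factory=lambda: {v: dict(d) for v, d in DEFAULT_TOXIN_CV.items()})
    censoring_limit_ng_ml: float = Field(0.5, ge=0)
    run_level_cv: float = Field(0.0, ge=0)

    gas_truth: dict = Field(default_factory=lambda: dict(DEFAULT_GAS_TRUTH))
    substrate_dm_g: dict = Field(default_factory=lambda: dict(DEFAULT_SUBSTRATE_DM))
    headspace_ml: float = Field(106.0, gt=0)
    temp_c: float = 39.0
    gas_interval_h: float = Field(1.0 / 12.0, gt=0)
    gas_duration_h: float = Field(48.0, gt=0)
    gas_noise_sd_psi: float = Field(0.02, ge=0)
    blank_drift_psi_per_h: float = Field(0.01, ge=0)
    n_blanks: int = 4

    metabolite_anchors: dict = Field(
        default_factory=lambda: {a: dict(d) for a, d in DEFAULT_METABOLITE_ANCHORS.items()}
    )
    metabolite_noise_scale: float = Field(1.0, ge=0)
    toxin_cv_scale: float = Field(1.0, ge=0)

    def validated(self) -> "ExperimentConfig":
        if not self.sampling_grid or self.sampling_grid[0] != 0:
            raise ValueError("sampling grid must start at 0 h")
        return self


@dataclass
class SyntheticDataset:
    """One generated experiment plus the truth that generated it."""

    toxins: pd.DataFrame | None = None
    gas_curves: list[GasCurve] = field(default_factory=list)
    gas_blanks: list[GasCurve] = field(default_factory=list)
    metabolites: pd.DataFrame | None = None
    metabolite_blanks: pd.DataFrame | None = None
    truth: dict = field(default_factory=dict)


def _fermenter_rng(seed: int, tag: int, run: int, variant: str, medium: str, dup: int):
    """Independent, reproducible stream per fermenter and data kind."""
    vkey = sum(ord(ch) * 31**i for i, ch in enumerate(variant)) % (2**16)
    mkey = 0 if medium == "vital" else 1
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(seed), tag, run, vkey, mkey, dup))
    )


def _lognormal_factors(rng, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with unit mean and the requested CV."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def _to_ng_ml(values: np.ndarray, unit: str) -> np.ndarray:
    return values * 1000.0 if unit in ("ug/mL", "µg/mL") else values


def generate_toxin_experiment(config: ExperimentConfig, seed: int) -> SyntheticDataset:
    """Generate the toxin concentration series of one experiment.

    SMS HGA/HGB trajectories come from the conversion-clearance model, PCM
    (and SMS MCPrG) from single-exponential decay; autoclaved-medium
    controls use rate constants attenuated by ``autoclaved_attenuation``.
    All values are emitted in ng/mL; observations below the censoring limit
    are flagged and carry the limit value.
    """
    config = config.validated()
    rows = []
    limit = config.censoring_limit_ng_ml

    def emit(run, dup, variant, medium, grid, analyte, model_values_ng, rng, cv):
        noisy = model_values_ng * _lognormal_factors(rng, cv * config.toxin_cv_scale, len(grid))
        for t, v in zip(grid, noisy):
            censored = v < limit
            rows.append(
                dict(
                    run=f"R{run+1}", fermenter=f"{variant}-{medium}-R{run+1}-F{dup+1}",
                    variant=variant, medium=medium, time_h=float(t),
                    analyte=analyte, value=float(limit if censored else v),
                    unit="ng/mL", censored=bool(censored),
                )
            )

    media = ["vital"] + (["autoclaved"] if config.include_autoclaved else [])
    for run in range(config.n_runs):
        for variant in config.variants:
            for medium in media:
                if medium == "autoclaved" and variant == "CSM":
                    continue
                grid = np.asarray(
                    config.sampling_grid if medium == "vital" else config.autoclaved_grid
                )
                atten = 1.0 if medium == "vital" else config.autoclaved_attenuation
                for dup in range(config.n_duplicates):
                    rng = _fermenter_rng(seed, 0, run, variant, medium, dup)
                    conv = config.conversion_truth.get(variant)
                    if conv is not None:
                        p = ToxinKineticParams(
                            hga0=conv["hga0"], hgb0=conv["hgb0"],
                            k=max(conv["k"] * atten, 1e-12), l=conv["l"] * atten,
                            unit=conv.get("unit", "ug/mL"),
                        )
                        hga = _to_ng_ml(np.asarray(hga_at(p, grid)), p.unit)
                        hgb = _to_ng_ml(np.asarray(hgb_at(p, grid)), p.unit)
                        cvs = config.toxin_cv.get(variant, {})
                        emit(run, dup, variant, medium, grid, "HGA", hga, rng, cvs.get("HGA", 0.0))
                        emit(run, dup, variant, medium, grid, "HGB", hgb, rng, cvs.get("HGB", 0.0))
                    for analyte, d in config.decay_truth.get(variant, {}).items():
                        vals = d["c0"] * np.exp(-d["k"] * atten * grid)
                        vals = _to_ng_ml(vals, d.get("unit", "ng/mL"))
                        cv = config.toxin_cv.get(variant, {}).get(analyte, 0.0)
                        emit(run, dup, variant, medium, grid, analyte, vals, rng, cv)

    truth = {
        "conversion": config.conversion_truth,
        "decay": config.decay_truth,
        "cv": config.toxin_cv,
        "censoring_limit_ng_ml": limit,
        "seed": int(seed),
    }
    toxins = pd.DataFrame(
        rows, columns=["run", "fermenter", "variant", "medium", "time_h",
                       "analyte", "value", "unit", "censored"],
    )
    return SyntheticDataset(toxins=toxins, truth=truth)


def _gas_grid(config: ExperimentConfig) -> np.ndarray:
    n = int(round(config.gas_duration_h / config.gas_interval_h))
    return np.linspace(0.0, n * config.gas_interval_h, n + 1)


def generate_gas_curves(config: ExperimentConfig, seed: int) -> SyntheticDataset:
    """Generate native-resolution cumulative pressure curves plus blanks.

    The substrate signal is the per-variant Gompertz truth scaled by the
    substrate dry matter and inverted through the ideal-gas conversion; a
    linear blank background drift is added to tests and blanks alike, then
    additive Gaussian recording noise.
    """
    config = config.validated()
    grid = _gas_grid(config)
    curves, blanks = [], []

    def background(t):
        return config.blank_drift_psi_per_h * t

    for run in range(config.n_runs):
        for variant in config.variants:
            truth = config.gas_truth[variant]
            gp = GompertzParams(*truth)
            dm = config.substrate_dm_g[variant]
            vol = np.asarray(gompertz_value(gp, grid)) * dm  # mL
            press = volume_to_pressure(vol, config.headspace_ml, config.temp_c)
            for dup in range(config.n_duplicates):
                rng = _fermenter_rng(seed, 1, run, variant, "vital", dup)
                noise = rng.normal(0.0, config.gas_noise_sd_psi, size=grid.size)
                curves.append(
                    GasCurve(
                        run=f"R{run+1}", fermenter=f"{variant}-gas-R{run+1}-F{dup+1}",
                        variant=variant, times=grid,
                        values=press + background(grid) + noise,
                        value_unit="psi", headspace_ml=config.headspace_ml,
                        temp_c=config.temp_c, substrate_dm_g=dm,
                    )
                )
        for blank_i in range(config.n_blanks):
            rng = _fermenter_rng(seed, 1, run, "BLK", "vital", blank_i)
            noise = rng.normal(0.0, config.gas_noise_sd_psi, size=grid.size)
            blanks.append(
                GasCurve(
                    run=f"R{run+1}", fermenter=f"BLK-gas-R{run+1}-F{blank_i+1}",
                    variant="BLK", times=grid, values=background(grid) + noise,
                    value_unit="psi", headspace_ml=config.headspace_ml,
                    temp_c=config.temp_c, substrate_dm_g=0.0,
                )
            )

    truth = {"gas": {v: tuple(p) for v, p in config.gas_truth.items()},
             "substrate_dm_g": dict(config.substrate_dm_g), "seed": int(seed)}
    return SyntheticDataset(gas_curves=curves, gas_blanks=blanks, truth=truth)


def _shape_weight(config: ExperimentConfig, variant: str, t: np.ndarray) -> np.ndarray:
    """Normalised cumulative-gas shape used to interpolate anchors in time."""
    gp = GompertzParams(*config.gas_truth[variant])
    g = np.asarray(gompertz_value(gp, t))
    g0 = float(gompertz_value(gp, 0.0))
    g48 = float(gompertz_value(gp, config.gas_duration_h))
    return (g - g0) / (g48 - g0)


def generate_metabolite_profiles(config: ExperimentConfig, seed: int) -> SyntheticDataset:
    """Generate pH/redox/SCFA/NH3 profiles plus blank NH3 measurements.

    Each trajectory interpolates the variant's 0 h and 48 h anchors along
    the variant's normalised gas-production shape.  NH3 is generated as a
    raw concentration (blank background plus the anchored difference) so
    that the blank-difference operation recovers the anchors; pH draws are
    clamped to the physiological [6.0, 8.0] window.
    """
    config = config.validated()
    grid = np.asarray(config.sampling_grid)
    rows, blank_rows = [], []
    nh3_background = BLANK_NH3_0 + (BLANK_NH3_48 - BLANK_NH3_0) * grid / config.gas_duration_h

    for run in range(config.n_runs):
        for variant in config.variants:
            w = _shape_weight(config, variant, grid)
            for dup in range(config.n_duplicates):
                rng = _fermenter_rng(seed, 2, run, variant, "vital", dup)
                ferm = f"{variant}-met-R{run+1}-F{dup+1}"
                for analyte, by_variant in config.metabolite_anchors.items():
                    if variant not in by_variant:
                        continue
                    v0, v48, sd = by_variant[variant]
                    mean = v0 + (v48 - v0) * w
                    if analyte == "NH3":
                        mean = mean + nh3_background
                    vals = mean + rng.normal(0.0, sd * config.metabolite_noise_scale, size=grid.size)
                    if analyte == "pH":
                        vals = np.clip(vals, 6.0, 8.0)
                    for t, v in zip(grid, vals):
                        rows.append(dict(run=f"R{run+1}", fermenter=ferm, variant=variant,
                                         time_h=float(t), analyte=analyte, value=float(v)))
        for blank_i in range(config.n_blanks):
            rng = _fermenter_rng(seed, 2, run, "BLK", "vital", blank_i)
            sd = config.metabolite_anchors["NH3"].get("CSM", (0, 0, 0.5))[2]
            vals = nh3_background + rng.normal(0.0, sd * config.metabolite_noise_scale, size=grid.size)
            for t, v in zip(grid, vals):
                blank_rows.append(dict(run=f"R{run+1}", fermenter=f"BLK-met-R{run+1}-F{blank_i+1}",
                                       variant="BLK", time_h=float(t), analyte="NH3", value=float(v)))

    cols = ["run", "fermenter", "variant", "time_h", "analyte", "value"]
    truth = {"anchors": config.metabolite_anchors,
             "nh3_background": [BLANK_NH3_0, BLANK_NH3_48], "seed": int(seed)}
    return SyntheticDataset(
        metabolites=pd.DataFrame(rows, columns=cols),
        metabolite_blanks=pd.DataFrame(blank_rows, columns=cols),
        truth=truth,
    )


def generate_dataset(config: ExperimentConfig, seed: int) -> SyntheticDataset:
    """Generate the complete experiment (toxins, gas, metabolites).

    The combined metabolite table additionally carries the vital-medium
    toxin concentrations (ng/mL) of the same fermenter duplicates, so the
    correlation stage can pair toxins with fermentation parameters.
    """
    tox = generate_toxin_experiment(config, seed)
    gas = generate_gas_curves(config, seed)
    met = generate_metabolite_profiles(config, seed)

    vital = tox.toxins[tox.toxins["medium"] == "vital"]
    tox_rows = pd.DataFrame(
        {
            "run": vital["run"],
            "fermenter": vital["fermenter"].str.replace("-vital-", "-met-", regex=False),
            "variant": vital["variant"],
            "time_h": vital["time_h"],
            "analyte": vital["analyte"],
            "value": vital["value"],
        }
    )
    combined = pd.concat([met.metabolites, tox_rows], ignore_index=True)
    return SyntheticDataset(
        toxins=tox.toxins,
        gas_curves=gas.gas_curves,
        gas_blanks=gas.gas_blanks,
        metabolites=combined,
        metabolite_blanks=met.metabolite_blanks,
        truth={"toxins": tox.truth, "gas": gas.truth, "metabolites": met.truth},
    )
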