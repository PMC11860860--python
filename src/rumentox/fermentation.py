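"""Microbial-metabolite summaries and the three-family correlation stage.

Covers the blank-referenced ammonia difference, the per-fermenter
acetic:propionic (C2:C3) ratio, and Pearson / Spearman / Kendall tau-b
correlation matrices between toxin concentrations and fermentation
parameters at a chosen sampling time (24 h by default, before toxins fall
below the measurement range).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MetaboliteTable, validate_metabolite_frame

__all__ = [
    "nh3_difference",
    "c2_c3_ratio",
    "correlation_matrix",
    "significance_stars",
    "correlation_wide_table",
]

METHODS = ("pearson", "spearman", "kendall")

#: significance thresholds rendered as *, **, ***
STAR_LEVELS = (0.05, 0.01, 0.001)


def nh3_difference(test: MetaboliteTable, blanks: MetaboliteTable) -> MetaboliteTable:
    """Express ammonia as test-fermenter minus mean-blank concentration.

    Buffer and inoculum contribute background NH3, so the net microbial
    contribution is the difference against the blank fermenters at the same
    sampling time.  Negative differences (net ammonia incorporation into
    microbial protein) are preserved.
    """
    test = validate_metabolite_frame(test)
    blanks = validate_metabolite_frame(blanks)
    t_nh3 = test[test["analyte"] == "NH3"].copy()
    b_nh3 = blanks[blanks["analyte"] == "NH3"]
    if t_nh3.empty:
        return t_nh3
    blank_mean = b_nh3.groupby("time_h")["value"].mean()
    missing = sorted(set(t_nh3["time_h"]) - set(blank_mean.index))
    if missing:
        raise ValueError(f"no blank NH3 measurements at time(s) {missing}")
    t_nh3["value"] = t_nh3["value"].to_numpy() - blank_mean.loc[t_nh3["time_h"]].to_numpy()
    return t_nh3


def c2_c3_ratio(table: MetaboliteTable) -> MetaboliteTable:
    """Append the per-fermenter acetic:propionic ratio as analyte ``C2:C3``.

    The ratio is formed within each fermenter and sampling time before any
    averaging happens downstream.  A zero propionic denominator yields a
    missing value rather than infinity.
    """
    table = validate_metabolite_frame(table)
    keys = ["run", "fermenter", "variant", "time_h"]
    wide = (
        table[table["analyte"].isin(["acetic", "propionic"])]
        .pivot_table(index=keys, columns="analyte", values="value", aggfunc="first")
        .reset_index()
    )
    if "acetic" not in wide.columns or "propionic" not in wide.columns:
        raise ValueError("need both acetic and propionic records to form C2:C3")
    wide = wide.dropna(subset=["acetic", "propionic"])
    denom = wide["propionic"].to_numpy()
    ratio = np.where(denom != 0, wide["acetic"].to_numpy() / np.where(denom != 0, denom, 1.0), np.nan)
    out = wide[keys].copy()
    out["analyte"] = "C2:C3"
    out["value"] = ratio
    return pd.concat([table, out.dropna(subset=["value"])], ignore_index=True)


def _pairwise_corr(x: np.ndarray, y: np.ndarray, method: str):
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "kendall":
        # tau-b with tie correction; two-sided normal approximation
        res = stats.kendalltau(x, y, variant="b", method="asymptotic")
        r, p = res.statistic, res.pvalue
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def correlation_matrix(
    table: MetaboliteTable,
    time_h: float = 24.0,
    method: str = "pearson",
    analytes: list[str] | None = None,
) -> pd.DataFrame:
    """All-pairs correlation of analytes measured at one sampling time.

    Observations are paired per fermenter (pairwise-complete: a pair uses
    every fermenter in which both analytes were measured).  Constant columns
    have undefined correlation and are reported as missing (NaN) rather than
    raising.  Returns a long table (method, var1, var2, r, p, n), symmetric
    with a unit diagonal.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    table = validate_metabolite_frame(table)
    at_t = table[np.isclose(table["time_h"].astype(float), time_h)]
    wide = at_t.pivot_table(
        index=["run", "fermenter"], columns="analyte", values="value", aggfunc="first"
    )
    cols = analytes if analytes is not None else sorted(wide.columns)
    rows = []
    for i, v1 in enumerate(cols):
        for v2 in cols[i:]:
            sub = wide[[v1, v2]].dropna() if v1 != v2 else wide[[v1]].dropna()
            n = len(sub)
            if v1 == v2:
                r, p = (1.0, 0.0) if n else (np.nan, np.nan)
            elif n < 3:
                raise ValueError(f"fewer than 3 paired observations for ({v1}, {v2})")
            else:
                x, y = sub[v1].to_numpy(), sub[v2].to_numpy()
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    r, p = np.nan, np.nan
                else:
                    r, p = _pairwise_corr(x, y, method)
            rows.append((method, v1, v2, r, p, n))
            if v1 != v2:
                rows.append((method, v2, v1, r, p, n))
    return pd.DataFrame(rows, columns=["method", "var1", "var2", "r", "p", "n"])


def significance_stars(p: float) -> str:
    """Render a p-value with the conventional star annotation."""
    if not np.isfinite(p):
        return ""
    stars = sum(p < level for level in STAR_LEVELS)
    return "*" * stars


def correlation_wide_table(long: pd.DataFrame, row_vars: list[str], col_vars: list[str]) -> pd.DataFrame:
    """Star-annotated wide view of a long correlation table."""
    out = pd.DataFrame(index=row_vars, columns=col_vars, dtype=object)
    lookup = long.set_index(["var1", "var2"])
    for rv in row_vars:
        for cv in col_vars:
            try:
                rec = lookup.loc[(rv, cv)]
            except KeyError:
                out.loc[rv, cv] = ""
                continue
            r, p = float(rec["r"]), float(rec["p"])
            out.loc[rv, cv] = f"{r:.2f} {significance_stars(p)}".strip() if np.isfinite(r) else "nd"
    return out
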