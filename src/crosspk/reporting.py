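"""Rounding and table formatting mirroring phase-I PK reporting style.

Summary tables show geometric mean (CV%) for exposure parameters, median
(range) for tmax and arithmetic mean (SD) for half-life and clearances;
rounding is half-up, 3 significant figures for AUC/Cmax, 1 decimal place
for ratios, t1/2 and clearances, 2 decimal places for tmax.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .nca import geometric_summary

__all__ = [
    "round_half_up",
    "round_sig",
    "format_value",
    "summarize_nca",
    "format_nca_summary",
    "ratio_table",
]


def round_half_up(value: float, decimals: int = 0) -> float:
    """Decimal round-half-up (5 rounds away from zero), as tables print."""
    if value is None or not math.isfinite(value):
        return value
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(value: float, sig: int = 3) -> float:
    """Half-up rounding to ``sig`` significant figures."""
    if value is None or not math.isfinite(value) or value == 0:
        return value
    exponent = math.floor(math.log10(abs(value)))
    return round_half_up(value, sig - 1 - exponent)


def format_value(value: float | None, kind: str) -> str:
    """Render one number with the profile used for its parameter kind."""
    if value is None or (isinstance(value, float) and not math.isfinite(value)):
        return "N/A"
    if kind == "exposure":  # AUC, Cmax: 3 significant figures
        v = round_sig(value, 3)
        return f"{v:g}"
    if kind == "ratio1dp":  # ratios, t1/2, CL: 1 decimal place
        return f"{round_half_up(value, 1):.1f}"
    if kind == "tmax":
        return f"{round_half_up(value, 2):.2f}"
    raise ValueError(f"unknown format kind {kind!r}")


_EXPOSURE = ("cmax", "auc_tau", "auc_last", "auc_inf")
_ARITH = ("half_life", "cl", "clr")


def summarize_nca(results: pd.DataFrame) -> pd.DataFrame:
    """Numeric per-(analyte, treatment, day) summaries of an NCA results frame.

    Exposure parameters get geometric mean and geometric CV%; tmax median
    and range; half-life and clearances arithmetic mean and SD.  Profiles
    whose gates suppressed a parameter simply drop out of that parameter's
    summary (their count is reported in ``n_<param>``).
    """
    rows = []
    for (analyte, treatment, day), grp in results.groupby(
        ["analyte", "treatment", "day"], sort=True
    ):
        row: dict = {"analyte": analyte, "treatment": treatment, "day": day,
                     "n": len(grp)}
        for param in _EXPOSURE:
            vals = grp[param].dropna()
            vals = vals[vals > 0]
            row[f"n_{param}"] = len(vals)
            if len(vals) > 0:
                s = geometric_summary(vals.to_numpy())
                row[f"{param}_gm"] = s.geometric_mean
                row[f"{param}_gcv"] = s.geometric_cv_percent
        tmax = grp["tmax"].dropna()
        if len(tmax) > 0:
            row["tmax_median"] = float(tmax.median())
            row["tmax_min"] = float(tmax.min())
            row["tmax_max"] = float(tmax.max())
        for param in _ARITH:
            vals = grp[param].dropna()
            row[f"n_{param}"] = len(vals)
            if len(vals) > 0:
                row[f"{param}_mean"] = float(vals.mean())
                row[f"{param}_sd"] = (float(vals.std(ddof=1))
                                      if len(vals) > 1 else None)
        rows.append(row)
    return pd.DataFrame(rows)


def format_nca_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Human-readable table: 'gm (CV%)', 'median (min-max)', 'mean (SD)'."""
    rows = []
    for _, r in summary.iterrows():
        out = {"analyte": r["analyte"], "treatment": r["treatment"],
               "day": int(r["day"]), "n": int(r["n"])}
        for param in _EXPOSURE:
            gm = r.get(f"{param}_gm")
            if gm is not None and not pd.isna(gm):
                gcv = r.get(f"{param}_gcv")
                cv_txt = ("" if gcv is None or pd.isna(gcv)
                          else f" ({round_half_up(gcv, 1):.1f})")
                out[param] = f"{format_value(gm, 'exposure')}{cv_txt}"
            else:
                out[param] = "N/A"
        if not pd.isna(r.get("tmax_median", float("nan"))):
            out["tmax"] = (
                f"{format_value(r['tmax_median'], 'tmax')} "
                f"({format_value(r['tmax_min'], 'tmax')}-"
                f"{format_value(r['tmax_max'], 'tmax')})"
            )
        else:
            out["tmax"] = "N/A"
        for param in _ARITH:
            mean = r.get(f"{param}_mean")
            if mean is not None and not pd.isna(mean):
                sd = r.get(f"{param}_sd")
                sd_txt = ("" if sd is None or pd.isna(sd)
                          else f" ({round_half_up(sd, 1):.1f})")
                out[param] = f"{format_value(mean, 'ratio1dp')}{sd_txt}"
            else:
                out[param] = "N/A"
        rows.append(out)
    return pd.DataFrame(rows)


def ratio_table(results) -> pd.DataFrame:
    """Ratio results as a tidy frame (one row per parameter/day contrast)."""
    rows = []
    for r in results:
        d = r.to_dict()
        d["ratio_percent"] = round_half_up(d["ratio_percent"], 1)
        d["ci_low_percent"] = round_half_up(d["ci_low_percent"], 1)
        d["ci_high_percent"] = round_half_up(d["ci_high_percent"], 1)
        rows.append(d)
    return pd.DataFrame(rows)
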