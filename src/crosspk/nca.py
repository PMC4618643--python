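"""Noncompartmental analysis (NCA) of plasma and urine profiles.

Implements the derived-parameter rules used for IV-infusion phase I data:

* Cmax / tmax by direct observation (earliest time on ties);
* AUC by the linear-up / log-down trapezoidal rule, with partial last
  segments interpolated by the same rule (AUC(0-tau), AUC(0-last));
* terminal slope lambda_z by log-linear OLS over the last k points strictly
  after tmax, k chosen by maximal adjusted R^2 (ties broken toward more
  points), gated at R^2 >= 0.8;
* extrapolation AUC(0-inf) = AUC(0-last) + Clast/lambda_z, suppressed when
  the extrapolated fraction exceeds 20%;
* CL = dose / AUC(0-inf), t1/2 = ln2 / lambda_z, CLR = amount excreted in
  urine over an interval divided by the plasma AUC over the same interval;
* accumulation ratio AUMtau(ss)/AUCtau(day 1) and linearity index
  AUCtau(ss)/AUC(0-inf, day 1);
* geometric summaries with geometric CV% = 100*sqrt(exp(s^2)-1), s the
  sample SD of the natural-log data.

When a gate fails the affected parameters (AUC(0-inf), t1/2, CL and the
linearity index) are withheld and the reason recorded in ``flags``;
Cmax, tmax, AUC(0-tau), AUC(0-last) and CLR remain reportable.

BLQ policy: leading below-limit samples (before the first quantifiable
concentration) enter the AUC grid as zero; embedded and trailing BLQ
samples are excluded from both the AUC grid and the lambda_z fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "NcaResult",
    "LambdaZFit",
    "SummaryStats",
    "DerivedRatios",
    "compute_cmax_tmax",
    "auc_lin_up_log_down",
    "auc_between",
    "fit_lambda_z",
    "extrapolate_auc",
    "prepare_profile",
    "nca_profile",
    "accumulation_and_linearity",
    "geometric_summary",
    "nca_dataset",
]

RSQ_THRESHOLD = 0.8
EXTRAPOLATION_LIMIT = 0.20


class DataError(ValueError):
    """Malformed profile data (unsorted times, negative concentrations...)."""


# ---------------------------------------------------------------------------
# elementary operations


def compute_cmax_tmax(times: Sequence[float], concs: Sequence[float]) -> tuple[float, float]:
    """Maximum observed concentration and its time; ties go to the earliest time."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.size == 0:
        raise DataError("profile has no quantifiable points")
    i = int(np.argmax(c))  # argmax returns the first maximum -> earliest time
    return float(c[i]), float(t[i])


def _segment_area(t1: float, c1: float, t2: float, c2: float) -> float:
    """Linear-up/log-down trapezoid for one segment."""
    dt = t2 - t1
    if c2 < c1 and c1 > 0.0 and c2 > 0.0:
        return dt * (c1 - c2) / math.log(c1 / c2)
    return dt * 0.5 * (c1 + c2)


def _segment_interp(t1: float, c1: float, t2: float, c2: float, t: float) -> float:
    """Concentration at ``t`` inside a segment, by the rule used for its area."""
    frac = (t - t1) / (t2 - t1)
    if c2 < c1 and c1 > 0.0 and c2 > 0.0:
        return c1 * (c2 / c1) ** frac
    return c1 + (c2 - c1) * frac


def auc_between(times: Sequence[float], concs: Sequence[float], t0: float, t1: float) -> float:
    """Linear-up/log-down AUC over ``[t0, t1]`` on an observed grid.

    ``t0`` and ``t1`` must lie within the sampled span; boundaries falling
    inside a segment are handled by interpolating with that segment's rule.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.size < 2:
        raise DataError("need at least two points for an AUC")
    if np.any(np.diff(t) <= 0):
        raise DataError("times must be strictly increasing")
    if np.any(c < 0):
        raise DataError("concentrations must be nonnegative")
    eps = 1e-9
    if t0 < t[0] - eps or t1 > t[-1] + eps:
        raise DataError("integration limits outside the sampled span")
    if t1 <= t0:
        raise DataError("t1 must exceed t0")
    t0 = min(max(t0, t[0]), t[-1])
    t1 = min(max(t1, t[0]), t[-1])
    area = 0.0
    for i in range(t.size - 1):
        a, b = t[i], t[i + 1]
        if b <= t0 or a >= t1:
            continue
        lo, hi = max(a, t0), min(b, t1)
        c_lo = c[i] if lo == a else _segment_interp(a, c[i], b, c[i + 1], lo)
        c_hi = c[i + 1] if hi == b else _segment_interp(a, c[i], b, c[i + 1], hi)
        area += _segment_area(lo, c_lo, hi, c_hi)
    return area


def auc_lin_up_log_down(
    times: Sequence[float], concs: Sequence[float], t_end: float | None = None
) -> float:
    """Linear-up/log-down AUC from the first sample to ``t_end`` (default: last)."""
    t = np.asarray(times, dtype=float)
    if t_end is None:
        t_end = float(t[-1])
    return auc_between(times, concs, float(t[0]), t_end)


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal log-linear regression result."""

    lambda_z: float | None
    rsq: float | None
    adj_rsq: float | None
    n_points: int
    t_first: float | None
    t_last: float | None
    reportable: bool
    reason: str | None = None

    @property
    def half_life(self) -> float | None:
        if self.lambda_z is None:
            return None
        return math.log(2.0) / self.lambda_z


def fit_lambda_z(
    times: Sequence[float],
    concs: Sequence[float],
    *,
    tmax: float | None = None,
    min_points: int = 3,
    max_points: int = 8,
    rsq_threshold: float = RSQ_THRESHOLD,
    adj_rsq_tol: float = 1e-4,
) -> LambdaZFit:
    """Fit the terminal elimination rate constant lambda_z.

    Candidate point sets are the last k quantifiable points strictly after
    tmax, for k = ``min_points`` ... ``max_points``; the set with maximal
    adjusted R^2 wins, ties within ``adj_rsq_tol`` resolved toward more
    points.  Fits with a nonnegative slope are discarded; the winning fit is
    flagged not reportable when R^2 < ``rsq_threshold``.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if tmax is None:
        _, tmax = compute_cmax_tmax(t, c)
    mask = (t > tmax) & (c > 0.0)
    tt, cc = t[mask], c[mask]
    if tt.size < min_points:
        return LambdaZFit(None, None, None, int(tt.size), None, None, False,
                          reason="insufficient-points")
    logc = np.log(cc)
    best: tuple[float, int, float, float] | None = None  # (adj, k, slope, rsq)
    for k in range(min_points, min(max_points, tt.size) + 1):
        x, y = tt[-k:], logc[-k:]
        xm, ym = x.mean(), y.mean()
        sxx = float(np.sum((x - xm) ** 2))
        sxy = float(np.sum((x - xm) * (y - ym)))
        syy = float(np.sum((y - ym) ** 2))
        if sxx == 0.0:
            continue
        slope = sxy / sxx
        if slope >= 0.0:
            continue
        rsq = 1.0 if syy == 0.0 else (sxy * sxy) / (sxx * syy)
        adj = 1.0 - (1.0 - rsq) * (k - 1) / (k - 2)
        if best is None or adj > best[0] + adj_rsq_tol or (
            abs(adj - best[0]) <= adj_rsq_tol and k > best[1]
        ):
            best = (adj, k, slope, rsq)
    if best is None:
        return LambdaZFit(None, None, None, int(tt.size), None, None, False,
                          reason="nonnegative-slope")
    adj, k, slope, rsq = best
    fit = LambdaZFit(
        lambda_z=-slope,
        rsq=rsq,
        adj_rsq=adj,
        n_points=k,
        t_first=float(tt[-k]),
        t_last=float(tt[-1]),
        reportable=rsq >= rsq_threshold,
        reason=None if rsq >= rsq_threshold else "rsq-below-threshold",
    )
    return fit


def extrapolate_auc(
    auc_last: float, c_last: float, lambda_z: float
) -> tuple[float, float, bool]:
    """AUC(0-inf), extrapolated fraction and the 20%-rule reportability flag."""
    if auc_last <= 0 or c_last <= 0 or lambda_z <= 0:
        raise DataError("auc_last, c_last and lambda_z must be positive")
    tail = c_last / lambda_z
    auc_inf = auc_last + tail
    fraction = tail / auc_inf
    return auc_inf, fraction, fraction <= EXTRAPOLATION_LIMIT


# ---------------------------------------------------------------------------
# profile-level assembly


def prepare_profile(
    times: Sequence[float],
    concs: Sequence[float],
    blq: Sequence[bool] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the BLQ policy and return the numeric (time, concentration) grid.

    Leading BLQ samples become zeros; embedded and trailing BLQ samples are
    dropped.  Concentrations for BLQ records may be NaN on input.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if blq is None:
        blq_arr = ~(np.isfinite(c) & (c > 0.0))
    else:
        blq_arr = np.asarray(blq, dtype=bool) | ~np.isfinite(c)
    if np.any(np.diff(t) <= 0):
        raise DataError("times must be strictly increasing")
    if np.any(c[~blq_arr] < 0):
        raise DataError("quantifiable concentrations must be nonnegative")
    quant = ~blq_arr
    if not np.any(quant):
        return np.empty(0), np.empty(0)
    first = int(np.argmax(quant))
    keep = quant.copy()
    keep[:first] = True  # leading BLQ -> zero
    out_c = np.where(blq_arr, 0.0, c)[keep]
    out_t = t[keep]
    # drop trailing/embedded BLQ beyond the last quantifiable point
    last_q = np.nonzero(quant[keep])[0][-1]
    return out_t[: last_q + 1], out_c[: last_q + 1]


@dataclass(frozen=True)
class NcaResult:
    """All per-profile NCA outputs with reportability flags."""

    analyte: str | None = None
    subject: object | None = None
    day: int | None = None
    treatment: str | None = None
    dose: float | None = None
    cmax: float | None = None
    tmax: float | None = None
    auc_last: float | None = None
    auc_tau: float | None = None
    auc_inf: float | None = None
    lambda_z: float | None = None
    rsq: float | None = None
    n_lambda_points: int = 0
    half_life: float | None = None
    cl: float | None = None
    clr: float | None = None
    extrapolated_fraction: float | None = None
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "analyte", "subject", "day", "treatment", "dose", "cmax", "tmax",
            "auc_last", "auc_tau", "auc_inf", "lambda_z", "rsq",
            "n_lambda_points", "half_life", "cl", "clr",
            "extrapolated_fraction",
        )}
        d["flags"] = ";".join(self.flags)
        return d


def nca_profile(
    times: Sequence[float],
    concs: Sequence[float],
    blq: Sequence[bool] | None = None,
    *,
    dose: float,
    tau: float | None = None,
    urine: pd.DataFrame | None = None,
    analyte: str | None = None,
    subject: object | None = None,
    day: int | None = None,
    treatment: str | None = None,
    max_lambda_points: int = 8,
) -> NcaResult:
    """Full NCA of one concentration-time profile.

    ``urine`` is an optional frame with columns ``interval_start``,
    ``interval_end`` and ``amount_excreted`` (hours relative to the same
    dose-start origin as ``times``); renal clearance is computed as the
    total amount excreted divided by the plasma AUC over the matching span.
    """
    if dose <= 0:
        raise DataError("dose must be positive")
    meta = dict(analyte=analyte, subject=subject, day=day, treatment=treatment,
                dose=dose)
    t, c = prepare_profile(times, concs, blq)
    if t.size == 0 or not np.any(c > 0):
        return NcaResult(flags=("not-evaluable",), **meta)
    flags: list[str] = []
    cmax, tmax = compute_cmax_tmax(t, c)
    # AUC to the last quantifiable concentration
    auc_last = auc_lin_up_log_down(t, c) if t.size >= 2 else None
    auc_tau = None
    if tau is not None and auc_last is not None:
        if tau <= t[-1] + 1e-9:
            auc_tau = auc_lin_up_log_down(t, c, t_end=min(tau, float(t[-1])))
        else:
            flags.append("tau-beyond-sampling")
    fit = fit_lambda_z(t, c, tmax=tmax, max_points=max_lambda_points)
    auc_inf = half_life = cl = frac = lambda_z = rsq = None
    if fit.lambda_z is not None:
        lambda_z, rsq = fit.lambda_z, fit.rsq
    if not fit.reportable:
        flags.append(f"lambda-z-{fit.reason}")
    elif auc_last is not None:
        auc_inf_val, frac_val, ok = extrapolate_auc(auc_last, float(c[-1]), fit.lambda_z)
        frac = frac_val
        if ok:
            auc_inf = auc_inf_val
            half_life = fit.half_life
            cl = dose / auc_inf
        else:
            flags.append("extrapolated-fraction-above-20pct")
    clr = None
    if urine is not None and len(urine) > 0 and auc_last is not None:
        span_end = min(float(urine["interval_end"].max()), float(t[-1]))
        sel = urine[urine["interval_end"] <= span_end + 1e-9]
        if len(sel) > 0 and span_end > t[0]:
            amount = float(sel["amount_excreted"].sum())
            auc_span = auc_between(t, c, max(0.0, float(t[0])), span_end)
            if auc_span > 0:
                clr = amount / auc_span
    return NcaResult(
        cmax=cmax, tmax=tmax, auc_last=auc_last, auc_tau=auc_tau,
        auc_inf=auc_inf, lambda_z=lambda_z, rsq=rsq,
        n_lambda_points=fit.n_points, half_life=half_life, cl=cl, clr=clr,
        extrapolated_fraction=frac, flags=tuple(flags), **meta,
    )


@dataclass(frozen=True)
class DerivedRatios:
    """Multiple-dose accumulation ratio and linearity index."""

    accumulation_ratio_auc_tau: float | None
    linearity_index: float | None
    flags: tuple[str, ...] = ()


def accumulation_and_linearity(day1: NcaResult, steady: NcaResult) -> DerivedRatios:
    """Accumulation ratio AUCtau(ss)/AUCtau(day1) and linearity index
    AUCtau(ss)/AUC(0-inf, day1)."""
    flags: list[str] = []
    acc = lin = None
    if day1.auc_tau and steady.auc_tau:
        acc = steady.auc_tau / day1.auc_tau
    else:
        flags.append("auc-tau-missing")
    if steady.auc_tau and day1.auc_inf:
        lin = steady.auc_tau / day1.auc_inf
    else:
        flags.append("day1-auc-inf-missing")
    return DerivedRatios(acc, lin, tuple(flags))


@dataclass(frozen=True)
class SummaryStats:
    """Geometric and arithmetic summaries of a positive-valued sample."""

    n: int
    geometric_mean: float
    geometric_cv_percent: float | None
    arithmetic_mean: float
    sd: float | None
    median: float
    range_min: float
    range_max: float


def geometric_summary(values: Sequence[float]) -> SummaryStats:
    """Summary with geometric CV% = 100*sqrt(exp(s^2)-1), s = SD of ln(values)."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise DataError("need at least one value")
    if np.any(v <= 0):
        raise DataError("geometric summaries need strictly positive values")
    logs = np.log(v)
    gm = float(np.exp(logs.mean()))
    if v.size >= 2:
        s = float(logs.std(ddof=1))
        gcv = 100.0 * math.sqrt(math.expm1(s * s))
        sd = float(v.std(ddof=1))
    else:
        gcv = None
        sd = None
    return SummaryStats(
        n=int(v.size), geometric_mean=gm, geometric_cv_percent=gcv,
        arithmetic_mean=float(v.mean()), sd=sd, median=float(np.median(v)),
        range_min=float(v.min()), range_max=float(v.max()),
    )


# ---------------------------------------------------------------------------
# dataset-level driver


def nca_dataset(
    concentrations: pd.DataFrame,
    doses: pd.DataFrame,
    urine: pd.DataFrame | None = None,
    *,
    tau: float = 8.0,
) -> pd.DataFrame:
    """Run :func:`nca_profile` for every (subject, period, analyte, day) profile.

    Expects the long-format frames written by :mod:`crosspk.synthetic`:
    sampling times are relative to the first infusion of each profile day,
    and each analyte's NCA clock is re-referenced to that analyte's own
    infusion start (relevant when components start at different offsets).
    The ``dose`` used for clearance is the amount of one administration of
    the analyte.
    """
    rows = []
    urine = urine if urine is not None else pd.DataFrame(
        columns=["subject", "period", "analyte", "day",
                 "interval_start", "interval_end", "amount_excreted"]
    )
    dose_key = doses.groupby(["subject", "period", "day", "analyte"])
    for (subject, period, day, analyte), grp in concentrations.groupby(
        ["subject", "period", "day", "analyte"], sort=True
    ):
        try:
            dgrp = dose_key.get_group((subject, period, day, analyte))
        except KeyError:
            continue  # no dose of this analyte that day -> no NCA profile
        amount = float(dgrp["amount"].iloc[0])
        day_doses = doses[
            (doses["subject"] == subject) & (doses["period"] == period)
            & (doses["day"] == day)
        ]
        day_ref = float(day_doses["start_time"].min())
        offset = float(dgrp["start_time"].min()) - day_ref
        grp = grp.sort_values("actual_time")
        t_rel = grp["actual_time"].to_numpy(dtype=float) - offset
        keep = t_rel >= -1e-9
        prof = grp.loc[keep]
        t_rel = np.clip(t_rel[keep], 0.0, None)
        ugrp = urine[
            (urine["subject"] == subject) & (urine["period"] == period)
            & (urine["day"] == day) & (urine["analyte"] == analyte)
        ]
        if len(ugrp) > 0 and offset != 0.0:
            ugrp = ugrp.assign(
                interval_start=np.clip(ugrp["interval_start"] - offset, 0.0, None),
                interval_end=ugrp["interval_end"] - offset,
            )
        res = nca_profile(
            t_rel,
            prof["concentration"].to_numpy(dtype=float),
            prof["blq"].to_numpy(dtype=bool),
            dose=amount,
            tau=tau,
            urine=ugrp if len(ugrp) > 0 else None,
            analyte=analyte,
            subject=subject,
            day=int(day),
            treatment=str(prof["treatment"].iloc[0]),
        )
        row = res.to_dict()
        row["period"] = period
        rows.append(row)
    frame = pd.DataFrame(rows)
    if len(frame) > 0:
        lead = ["subject", "period", "treatment", "analyte", "day"]
        frame = frame[lead + [c for c in frame.columns if c not in lead]]
        frame = frame.sort_values(lead).reset_index(drop=True)
    return frame
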