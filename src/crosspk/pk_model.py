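"""Closed-form compartmental models for constant-rate IV infusions.

Open one- and two-compartment disposition models with zero-order (constant
rate) input are solved in closed form as sums of exponentials.  They serve
two purposes in this package:

* forward engine for the synthetic crossover-study generator
  (:mod:`crosspk.synthetic`), and
* exact oracles for the noncompartmental analysis layer — the identities
  AUC(0-inf) = Dose/CL, cumulative urinary excretion = f_renal x Dose, and
  linear superposition over repeated doses hold to machine precision here,
  so NCA estimates can be checked against known truth.

Units are fixed throughout the package: time in hours, amounts in mg,
volumes in litres, clearances in L/h, concentrations in mg/L (= ug/mL).
Unit conversion, if any, belongs at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "InvalidParameterError",
    "IntervalError",
    "PkParameters",
    "DoseEvent",
    "Regimen",
    "infusion_concentration",
    "infusion_auc",
    "multi_dose_concentration",
    "multi_dose_auc",
    "cumulative_urine_amount",
]


class InvalidParameterError(ValueError):
    """A pharmacokinetic parameter is missing, non-positive or inconsistent."""


class IntervalError(ValueError):
    """A time interval is empty or reversed."""


@dataclass(frozen=True)
class PkParameters:
    """Disposition parameters of a 1- or 2-compartment IV model.

    The model order is inferred from the optional fields: supplying both
    ``peripheral_volume`` and ``intercompartmental_clearance`` selects the
    two-compartment model; supplying neither selects the one-compartment
    model.  ``renal_fraction`` is the fraction of total clearance that is
    renal, so CL_R = renal_fraction * clearance.
    """

    clearance: float
    central_volume: float
    peripheral_volume: float | None = None
    intercompartmental_clearance: float | None = None
    renal_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.clearance <= 0 or self.central_volume <= 0:
            raise InvalidParameterError(
                "clearance and central_volume must be positive"
            )
        optionals = (self.peripheral_volume, self.intercompartmental_clearance)
        if (optionals[0] is None) != (optionals[1] is None):
            raise InvalidParameterError(
                "peripheral_volume and intercompartmental_clearance must be "
                "supplied together (2-compartment) or both omitted"
            )
        if optionals[0] is not None:
            if optionals[0] <= 0 or optionals[1] <= 0:
                raise InvalidParameterError(
                    "2-compartment parameters must be positive"
                )
        if not 0.0 <= self.renal_fraction <= 1.0:
            raise InvalidParameterError("renal_fraction must lie in [0, 1]")

    @property
    def n_compartments(self) -> int:
        return 1 if self.peripheral_volume is None else 2

    @property
    def renal_clearance(self) -> float:
        return self.renal_fraction * self.clearance

    def disposition_exponentials(self) -> tuple[tuple[float, float], ...]:
        """Unit-bolus concentration as ``sum_i coef_i * exp(-rate_i * t)``.

        For one compartment this is the single term ``(1/V) e^{-kt}`` with
        k = CL/V.  For two compartments the usual alpha/beta macro constants
        are derived from the micro constants k10, k12, k21.
        """
        if self.n_compartments == 1:
            k = self.clearance / self.central_volume
            return ((1.0 / self.central_volume, k),)
        v1 = self.central_volume
        k10 = self.clearance / v1
        k12 = self.intercompartmental_clearance / v1
        k21 = self.intercompartmental_clearance / self.peripheral_volume
        s = k10 + k12 + k21
        disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
        alpha = 0.5 * (s + disc)
        beta = 0.5 * (s - disc)
        coef_a = (alpha - k21) / (v1 * (alpha - beta))
        coef_b = (k21 - beta) / (v1 * (alpha - beta))
        return ((coef_a, alpha), (coef_b, beta))

    @property
    def terminal_rate(self) -> float:
        """Terminal (slowest) disposition rate constant, i.e. lambda_z."""
        return min(rate for _, rate in self.disposition_exponentials())

    @property
    def terminal_half_life(self) -> float:
        return math.log(2.0) / self.terminal_rate


@dataclass(frozen=True)
class DoseEvent:
    """One constant-rate IV infusion of a single analyte."""

    drug: str
    amount: float  # mg
    start_time: float  # h
    infusion_duration: float  # h

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise InvalidParameterError("dose amount must be positive")
        if self.infusion_duration <= 0:
            raise InvalidParameterError(
                "infusion_duration must be positive (IV infusion only)"
            )
        if self.start_time < 0:
            raise InvalidParameterError("start_time must be nonnegative")

    @property
    def rate(self) -> float:
        """Zero-order input rate R0 = amount / duration (mg/h)."""
        return self.amount / self.infusion_duration


@dataclass(frozen=True)
class Regimen:
    """An ordered sequence of dose events plus the nominal dosing interval tau."""

    dose_events: tuple[DoseEvent, ...]
    tau: float = 8.0

    def __post_init__(self) -> None:
        if not self.dose_events:
            raise InvalidParameterError("regimen must contain at least one dose")
        if self.tau <= 0:
            raise InvalidParameterError("tau must be positive")
        starts = [d.start_time for d in self.dose_events]
        if any(b < a for a, b in zip(starts, starts[1:])):
            object.__setattr__(
                self,
                "dose_events",
                tuple(sorted(self.dose_events, key=lambda d: d.start_time)),
            )

    @classmethod
    def single(cls, dose: DoseEvent, tau: float = 8.0) -> "Regimen":
        return cls((dose,), tau=tau)

    def truncated(self, n_events: int) -> "Regimen":
        """Regimen restricted to its first ``n_events`` doses."""
        return Regimen(self.dose_events[:n_events], tau=self.tau)


def _as_array(t) -> tuple[np.ndarray, bool]:
    arr = np.asarray(t, dtype=float)
    return np.atleast_1d(arr), arr.ndim == 0


def infusion_concentration(params: PkParameters, dose: DoseEvent, t) -> np.ndarray | float:
    """Plasma concentration at time ``t`` for one infusion (ug/mL).

    Zero before the infusion starts; rises during the infusion; decays as a
    sum of exponentials afterwards.  Accepts scalars or arrays of times.
    """
    tt, scalar = _as_array(t)
    u = tt - dose.start_time
    big_t = dose.infusion_duration
    rate = dose.rate
    out = np.zeros_like(u)
    for coef, lam in params.disposition_exponentials():
        a = rate * coef / lam
        during = a * (1.0 - np.exp(-lam * np.clip(u, 0.0, big_t)))
        after = a * (1.0 - math.exp(-lam * big_t)) * np.exp(
            -lam * np.clip(u - big_t, 0.0, None)
        )
        out += np.where(u <= big_t, during, after)
    out[u <= 0.0] = 0.0
    return float(out[0]) if scalar else out


def _cumulative_auc_since_start(params: PkParameters, dose: DoseEvent, u: np.ndarray) -> np.ndarray:
    """AUC of one infusion from its start to ``u`` hours after the start."""
    big_t = dose.infusion_duration
    rate = dose.rate
    total = np.zeros_like(u)
    for coef, lam in params.disposition_exponentials():
        a = rate * coef / lam
        uc = np.clip(u, 0.0, big_t)
        during = a * (uc - (1.0 - np.exp(-lam * uc)) / lam)
        end_term = a / lam * (1.0 - math.exp(-lam * big_t))
        with np.errstate(invalid="ignore"):
            tail = end_term * (1.0 - np.exp(-lam * np.clip(u - big_t, 0.0, None)))
        total += during + np.where(u > big_t, tail, 0.0)
    total[u <= 0.0] = 0.0
    return total


def infusion_auc(params: PkParameters, dose: DoseEvent, t0: float, t1: float) -> float:
    """Exact AUC of a single infusion's curve over ``[t0, t1]`` (ug*h/mL).

    ``t1`` may be ``numpy.inf`` for the extrapolated-to-infinity area, in
    which case AUC(0-inf) = Dose/CL holds identically.
    """
    if t1 <= t0:
        raise IntervalError("t1 must exceed t0")
    u = np.array([t0 - dose.start_time, t1 - dose.start_time], dtype=float)
    f = _cumulative_auc_since_start(params, dose, u)
    return float(f[1] - f[0])


def multi_dose_concentration(params: PkParameters, regimen: Regimen, t) -> np.ndarray | float:
    """Superposition of all dose events' concentration curves at ``t``."""
    tt, scalar = _as_array(t)
    out = np.zeros_like(tt)
    for dose in regimen.dose_events:
        out += infusion_concentration(params, dose, tt)
    return float(out[0]) if scalar else out


def multi_dose_auc(params: PkParameters, regimen: Regimen, t0: float, t1: float) -> float:
    """Exact AUC of the superposed multi-dose curve over ``[t0, t1]``."""
    if t1 <= t0:
        raise IntervalError("t1 must exceed t0")
    return sum(infusion_auc(params, d, t0, t1) for d in regimen.dose_events)


def cumulative_urine_amount(
    params: PkParameters, regimen: Regimen, t0: float, t1: float
) -> float:
    """Amount excreted in urine over ``[t0, t1]`` (mg).

    Renal excretion rate is CL_R times the plasma concentration, so the
    interval amount is ``renal_fraction * CL * AUC(t0, t1)``.  Additive over
    adjacent intervals; over ``[0, inf)`` for a single dose it equals
    ``renal_fraction * dose`` (mass balance).
    """
    if t0 < 0:
        raise IntervalError("t0 must be nonnegative")
    if t1 <= t0:
        raise IntervalError("t1 must exceed t0")
    return params.renal_clearance * multi_dose_auc(params, regimen, t0, t1)
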