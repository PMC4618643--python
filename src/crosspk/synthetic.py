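"""Seeded synthetic crossover-study data generator.

Produces long-format plasma-concentration, urine-collection and dose-event
tables for the study designs in :mod:`crosspk.designs`, with the
variability structure the downstream statistical analysis assumes:

* between-subject variability — a subject-level log-normal multiplier on
  clearance with volumes co-scaled, which leaves all rate constants (and
  hence half-life and profile shape) unchanged and scales dose-normalised
  exposure log-normally;
* within-subject (period-level) variability — the same construction with
  an independent period-level multiplier of SD ``within_subject_sd_log``
  on the log scale, so the within-subject SD of log Cmax (and log AUC)
  equals that input exactly, matching the single-sigma_w parameterisation
  of the crossover power calculation;
* proportional assay noise on each measured concentration and urine
  amount;
* LLOQ censoring — concentrations below the analyte's lower limit of
  quantification are flagged BLQ and withheld from numeric use.

Urine amounts are derived from the plasma model by mass balance
(amount = f_renal * CL * AUC over the interval); because the exposure
multipliers scale CL and AUC inversely, interval amounts are invariant to
them, as mass balance requires.

Everything is driven by one master seed; per-(subject, period, analyte)
streams are derived deterministically, so a fixed seed reproduces the
output byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .designs import CrossoverDesign, DesignError, default_lloq, default_pk_parameters, default_within_subject_sd
from .pk_model import DoseEvent, PkParameters, Regimen, multi_dose_auc, multi_dose_concentration

__all__ = [
    "VariabilityModel",
    "StudyData",
    "generate_crossover_study",
    "apply_lloq",
    "censor_concentration",
    "write_study_csvs",
    "read_study_csvs",
    "CONC_COLUMNS",
    "URINE_COLUMNS",
    "DOSE_COLUMNS",
]

CONC_COLUMNS = ("subject", "sequence", "period", "treatment", "analyte", "day",
                "nominal_time", "actual_time", "concentration", "blq", "lloq")
URINE_COLUMNS = ("subject", "sequence", "period", "treatment", "analyte", "day",
                 "interval_start", "interval_end", "amount_excreted")
DOSE_COLUMNS = ("subject", "sequence", "period", "treatment", "analyte", "day",
                "amount", "start_time", "infusion_duration")


class DataError(ValueError):
    """Invalid record data."""


@dataclass(frozen=True)
class VariabilityModel:
    """Log-scale variance components and assay noise for one analyte.

    ``between_subject_sd_log`` and ``within_subject_sd_log`` are SDs of the
    subject- and period-level log exposure multipliers; ``residual_cv`` is
    the proportional assay noise applied per measurement.
    """

    between_subject_sd_log: float = 0.15
    within_subject_sd_log: float = 0.2088
    residual_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.between_subject_sd_log, self.within_subject_sd_log,
               self.residual_cv) < 0:
            raise DataError("variability SDs must be nonnegative")

    @classmethod
    def none(cls, seed: int = 0) -> "VariabilityModel":
        """Degenerate model: every profile equals the noiseless model curve."""
        return cls(0.0, 0.0, 0.0, seed)


@dataclass
class StudyData:
    """Generated study dataset: three long-format tables plus provenance."""

    concentrations: pd.DataFrame
    urine: pd.DataFrame
    doses: pd.DataFrame
    design_name: str
    seed: int


def censor_concentration(value: float, lloq: float) -> tuple[float, bool]:
    """Apply LLOQ censoring to one concentration.

    Values below the limit are BLQ (returned as NaN); the limit itself is
    quantifiable.  Negative inputs are rejected.
    """
    if lloq <= 0:
        raise DataError("lloq must be positive")
    if value < 0:
        raise DataError("concentration must be nonnegative")
    if value < lloq:
        return math.nan, True
    return value, False


def apply_lloq(frame: pd.DataFrame, lloq: float | dict[str, float]) -> pd.DataFrame:
    """Vectorised LLOQ censoring of a concentration table.

    ``lloq`` may be a scalar or an analyte -> limit mapping.  Returns a copy
    with ``blq`` set and BLQ concentrations replaced by NaN; the ``lloq``
    column records the limit applied to each row.
    """
    out = frame.copy()
    if isinstance(lloq, dict):
        limits = out["analyte"].map(lloq).astype(float)
        if limits.isna().any():
            missing = sorted(out.loc[limits.isna(), "analyte"].unique())
            raise DataError(f"no LLOQ for analytes {missing}")
    else:
        limits = pd.Series(float(lloq), index=out.index)
    if (limits <= 0).any():
        raise DataError("lloq must be positive")
    conc = out["concentration"].astype(float)
    if (conc.dropna() < 0).any():
        raise DataError("concentration must be nonnegative")
    blq = conc.isna() | (conc < limits)
    out["blq"] = blq
    out.loc[blq, "concentration"] = math.nan
    out["lloq"] = limits
    return out


def _treatment_regimens(design: CrossoverDesign) -> dict[str, dict[str, Regimen]]:
    """Per (treatment, analyte) multi-dose regimen over one period."""
    out: dict[str, dict[str, Regimen]] = {}
    for label, comps in design.treatments.items():
        per_analyte: dict[str, Regimen] = {}
        for comp in comps:
            events = tuple(
                DoseEvent(comp.analyte, comp.amount, slot + comp.offset, comp.duration)
                for slot in design.dose_times
            )
            per_analyte[comp.analyte] = Regimen(events, tau=design.tau)
        out[label] = per_analyte
    return out


def generate_crossover_study(
    design: CrossoverDesign,
    pk: dict[str, PkParameters] | None = None,
    variability: VariabilityModel | dict[str, VariabilityModel] | None = None,
    lloq: dict[str, float] | float | None = None,
    seed: int | None = None,
) -> StudyData:
    """Simulate the full study defined by ``design``.

    Parameters default to the package calibrations
    (:func:`crosspk.designs.default_pk_parameters` etc.).  ``seed``
    overrides the seed carried by ``variability``; pass
    ``VariabilityModel.none()`` for noiseless data.
    """
    analytes = design.analytes
    pk = pk or default_pk_parameters()
    for a in analytes:
        if a not in pk or pk[a] is None:
            raise DesignError(f"no PK parameters for analyte {a!r}")
    if variability is None:
        wsd = default_within_subject_sd()
        var_map = {a: VariabilityModel(within_subject_sd_log=wsd.get(a, 0.2088))
                   for a in analytes}
    elif isinstance(variability, VariabilityModel):
        var_map = {a: variability for a in analytes}
    else:
        var_map = dict(variability)
        for a in analytes:
            if a not in var_map:
                raise DesignError(f"no variability model for analyte {a!r}")
    if seed is None:
        any_var = next(iter(var_map.values()))
        seed = any_var.seed
    if lloq is None:
        lloq_map = {a: default_lloq().get(a, 1e-9) for a in analytes}
    elif isinstance(lloq, dict):
        lloq_map = dict(lloq)
    else:
        lloq_map = {a: float(lloq) for a in analytes}

    regimens = _treatment_regimens(design)
    analyte_index = {a: i for i, a in enumerate(sorted(analytes))}

    # Pre-compute noiseless template curves/amounts per (treatment, analyte):
    # subject and period multipliers only rescale them.
    conc_templates: dict[tuple[str, str], list[tuple[int, np.ndarray, np.ndarray]]] = {}
    urine_templates: dict[tuple[str, str], list[tuple[int, float, float, float]]] = {}
    for label, per_analyte in regimens.items():
        for analyte, regimen in per_analyte.items():
            templates = []
            for day, rel_times in sorted(design.sampling[label].items()):
                day_ref = design.day_start(day)
                abs_t = day_ref + np.asarray(rel_times, dtype=float)
                base = multi_dose_concentration(pk[analyte], regimen, abs_t)
                templates.append((day, np.asarray(rel_times, float), base))
            conc_templates[(label, analyte)] = templates
            u_templates = []
            fe_cl = pk[analyte].renal_clearance
            for day, intervals in sorted(design.urine_intervals.items()):
                day_ref = design.day_start(day)
                for (s, e) in intervals:
                    amount = fe_cl * multi_dose_auc(
                        pk[analyte], regimen, day_ref + s, day_ref + e
                    )
                    u_templates.append((day, s, e, amount))
            urine_templates[(label, analyte)] = u_templates

    conc_rows: list[tuple] = []
    urine_rows: list[tuple] = []
    dose_rows: list[tuple] = []
    for i in range(design.n_subjects):
        subject = i + 1
        sequence = design.sequence_for(i)
        seq_label = "/".join(sequence)
        eta = {
            a: np.random.default_rng((seed, 0, i, analyte_index[a])).normal(
                0.0, var_map[a].between_subject_sd_log
            )
            for a in analytes
        }
        for p, label in enumerate(sequence, start=1):
            for analyte, regimen in regimens[label].items():
                var = var_map[analyte]
                rng = np.random.default_rng((seed, 1, i, p, analyte_index[analyte]))
                eps = rng.normal(0.0, var.within_subject_sd_log)
                mult = math.exp(eta[analyte] + eps)
                limit = lloq_map[analyte]
                for day, rel_times, base in conc_templates[(label, analyte)]:
                    noise = (1.0 + var.residual_cv * rng.standard_normal(base.size)
                             if var.residual_cv > 0 else np.ones(base.size))
                    conc = np.clip(base * mult * noise, 0.0, None)
                    for t_rel, c in zip(rel_times, conc):
                        value, blq = censor_concentration(float(c), limit)
                        conc_rows.append(
                            (subject, seq_label, p, label, analyte, day,
                             float(t_rel), float(t_rel), value, blq, limit)
                        )
                for day, s, e, base_amount in urine_templates[(label, analyte)]:
                    noise = (1.0 + var.residual_cv * rng.standard_normal()
                             if var.residual_cv > 0 else 1.0)
                    urine_rows.append(
                        (subject, seq_label, p, label, analyte, day,
                         s, e, max(base_amount * noise, 0.0))
                    )
                for ev in regimen.dose_events:
                    dose_rows.append(
                        (subject, seq_label, p, label, analyte,
                         int(ev.start_time // 24.0) + 1,
                         ev.amount, ev.start_time, ev.infusion_duration)
                    )
    conc = pd.DataFrame(conc_rows, columns=list(CONC_COLUMNS))
    urine = pd.DataFrame(urine_rows, columns=list(URINE_COLUMNS))
    doses = pd.DataFrame(dose_rows, columns=list(DOSE_COLUMNS))
    return StudyData(conc, urine, doses, design.name, seed)


# ---------------------------------------------------------------------------
# CSV I/O (documented long formats; times rounded to 2 decimals)


def write_study_csvs(study: StudyData, outdir: str | Path) -> dict[str, Path]:
    """Write concentrations.csv, urine.csv and doses.csv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    conc = study.concentrations.copy()
    for col in ("nominal_time", "actual_time"):
        conc[col] = conc[col].map(lambda v: f"{v:.2f}")
    conc["concentration"] = conc["concentration"].map(
        lambda v: "" if pd.isna(v) else f"{v:.6g}"
    )
    conc["lloq"] = conc["lloq"].map(lambda v: f"{v:.6g}")
    urine = study.urine.copy()
    for col in ("interval_start", "interval_end"):
        urine[col] = urine[col].map(lambda v: f"{v:.2f}")
    urine["amount_excreted"] = urine["amount_excreted"].map(lambda v: f"{v:.6g}")
    doses = study.doses.copy()
    for col in ("start_time", "infusion_duration"):
        doses[col] = doses[col].map(lambda v: f"{v:.2f}")
    doses["amount"] = doses["amount"].map(lambda v: f"{v:.6g}")
    paths = {}
    for name, frame in (("concentrations", conc), ("urine", urine), ("doses", doses)):
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False, lineterminator="\n")
        paths[name] = path
    return paths


def read_study_csvs(
    conc_path: str | Path,
    urine_path: str | Path | None = None,
    dose_path: str | Path | None = None,
) -> StudyData:
    """Read the long-format CSVs back into a :class:`StudyData`."""
    conc = pd.read_csv(conc_path)
    conc["blq"] = conc["blq"].astype(bool)
    urine = (pd.read_csv(urine_path) if urine_path is not None
             else pd.DataFrame(columns=list(URINE_COLUMNS)))
    doses = (pd.read_csv(dose_path) if dose_path is not None
             else pd.DataFrame(columns=list(DOSE_COLUMNS)))
    return StudyData(conc, urine, doses, design_name="loaded", seed=-1)
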