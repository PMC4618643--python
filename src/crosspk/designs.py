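"""Preset study designs and default simulation calibration.

Three phase-I IV-infusion designs are provided:

``caz_avi_pk``
    Single-cohort multiple-dose design (n = 16): ceftazidime 2000 mg +
    avibactam 500 mg as 2-h infusions, a single dose on Days 1 and 11 and
    q8h dosing on Days 2-10, with rich sampling on Days 1, 4 and 11 and
    urine collection on Days 1 and 11.

``caz_avi_ddi``
    3-way crossover (n = 27) of ceftazidime 2000 mg, avibactam 500 mg and
    the combination, each period 4 days (single dose Days 1 and 4, q8h on
    Days 2-3), washout >= 48 h, sampling and urine on Days 1 and 4.

``caz_avi_mtz_ddi``
    3-way crossover (n = 28) of ceftazidime-avibactam, metronidazole
    500 mg (1-h infusion) and metronidazole followed by
    ceftazidime-avibactam; same 4-day dosing calendar.  In the combined
    arm the 2-h ceftazidime-avibactam infusion starts 1 h after the start
    of the metronidazole infusion.

The default disposition parameters are one-compartment calibrations that
reproduce the published clearance and terminal half-life of each analyte;
they are simulation calibration choices, not estimates (see
docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .pk_model import InvalidParameterError, PkParameters

__all__ = [
    "InfusionComponent",
    "CrossoverDesign",
    "DesignError",
    "caz_avi_pk",
    "caz_avi_ddi",
    "caz_avi_mtz_ddi",
    "replicate_design",
    "get_design",
    "default_pk_parameters",
    "default_within_subject_sd",
    "default_lloq",
    "ddi_contrasts",
    "DESIGNS",
    "DAY1_SCHEDULE",
    "URINE_INTERVALS",
]


class DesignError(ValueError):
    """Inconsistent crossover design specification."""


@dataclass(frozen=True)
class InfusionComponent:
    """One analyte's infusion within a treatment administration slot."""

    analyte: str
    amount: float  # mg
    duration: float  # h
    offset: float = 0.0  # h after the slot start


# Rich Day-1 blood-sampling schedule (hours after the start of the first
# infusion of the day); the 24-h sample doubles as the next day's predose.
DAY1_SCHEDULE = (0.0, 0.5, 1.0, 1.5, 2.0, 2.25, 2.5, 2.75, 3.0, 3.5, 4.0,
                 6.0, 8.0, 12.0, 24.0)
# Sparse steady-state schedule used on Day 4 of the multiple-dose design.
PK_DAY4_SCHEDULE = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
# Per-arm schedules of the metronidazole interaction study.
CAZAVI_SCHEDULE = (0.0, 0.5, 1.0, 1.5, 2.0, 2.25, 2.5, 2.75, 3.0, 4.0, 5.0,
                   7.0, 11.0, 23.0)
MTZ_SCHEDULE = (0.0, 0.5, 1.0, 1.25, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)
MTZ_COMBO_SCHEDULE = (0.0, 0.5, 1.0, 1.25, 1.5, 2.0, 2.5, 3.0, 3.25, 3.5,
                      3.75, 4.0, 5.0, 6.0, 8.0, 12.0, 24.0)

URINE_INTERVALS = ((0.0, 2.0), (2.0, 4.0), (4.0, 8.0), (8.0, 12.0), (12.0, 24.0))

#: Dosing calendar of a 4-day crossover period: single dose Day 1, q8h on
#: Days 2-3, single dose Day 4 -> 8 administrations per component.
FOUR_DAY_SLOTS = (0.0, 24.0, 32.0, 40.0, 48.0, 56.0, 64.0, 72.0)

_PK_STUDY_SLOTS = (0.0,) + tuple(
    24.0 * (d - 1) + 8.0 * j for d in range(2, 11) for j in range(3)
) + (240.0,)


@dataclass(frozen=True)
class CrossoverDesign:
    """A (possibly degenerate) crossover design with a shared dosing calendar.

    ``sampling`` maps treatment -> {day -> nominal sampling times (h)
    relative to the day's first infusion start}; ``urine_intervals`` maps
    day -> collection intervals, applied to every treatment.
    """

    name: str
    treatments: dict[str, tuple[InfusionComponent, ...]]
    sequences: tuple[tuple[str, ...], ...]
    n_subjects: int
    dose_times: tuple[float, ...]
    sampling: dict[str, dict[int, tuple[float, ...]]]
    urine_intervals: dict[int, tuple[tuple[float, float], ...]] = field(
        default_factory=dict
    )
    washout: float = 48.0
    tau: float = 8.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise DesignError("n_subjects must be >= 1")
        if self.washout < 48.0:
            raise DesignError("washout must be at least 48 h")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise DesignError("all sequences must have the same length")
        for seq in self.sequences:
            for label in seq:
                if label not in self.treatments:
                    raise DesignError(f"unknown treatment label {label!r}")
        for label in self.sampling:
            if label not in self.treatments:
                raise DesignError(f"sampling schedule for unknown treatment {label!r}")
        if any(b < a for a, b in zip(self.dose_times, self.dose_times[1:])):
            raise DesignError("dose_times must be sorted")

    @property
    def periods(self) -> int:
        return len(self.sequences[0])

    @property
    def analytes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for comps in self.treatments.values():
            for comp in comps:
                if comp.analyte not in seen:
                    seen.append(comp.analyte)
        return tuple(seen)

    def day_of_slot(self, slot_time: float) -> int:
        return int(slot_time // 24.0) + 1

    def day_start(self, day: int) -> float:
        starts = [t for t in self.dose_times if self.day_of_slot(t) == day]
        if not starts:
            raise DesignError(f"no administration on day {day}")
        return min(starts)

    def sequence_for(self, subject_index: int) -> tuple[str, ...]:
        return self.sequences[subject_index % len(self.sequences)]


def _all_orders(labels: tuple[str, ...]) -> tuple[tuple[str, ...], ...]:
    import itertools

    return tuple(itertools.permutations(labels))


def caz_avi_pk(n_subjects: int = 16) -> CrossoverDesign:
    comps = (
        InfusionComponent("ceftazidime", 2000.0, 2.0),
        InfusionComponent("avibactam", 500.0, 2.0),
    )
    sched = {1: DAY1_SCHEDULE, 4: PK_DAY4_SCHEDULE, 11: DAY1_SCHEDULE}
    return CrossoverDesign(
        name="caz_avi_pk",
        treatments={"CAZ-AVI": comps},
        sequences=(("CAZ-AVI",),),
        n_subjects=n_subjects,
        dose_times=_PK_STUDY_SLOTS,
        sampling={"CAZ-AVI": sched},
        urine_intervals={1: URINE_INTERVALS, 11: URINE_INTERVALS},
    )


def caz_avi_ddi(n_subjects: int = 27) -> CrossoverDesign:
    treatments = {
        "CAZ": (InfusionComponent("ceftazidime", 2000.0, 2.0),),
        "AVI": (InfusionComponent("avibactam", 500.0, 2.0),),
        "CAZ-AVI": (
            InfusionComponent("ceftazidime", 2000.0, 2.0),
            InfusionComponent("avibactam", 500.0, 2.0),
        ),
    }
    sched = {1: DAY1_SCHEDULE, 4: DAY1_SCHEDULE}
    return CrossoverDesign(
        name="caz_avi_ddi",
        treatments=treatments,
        sequences=_all_orders(("CAZ", "AVI", "CAZ-AVI")),
        n_subjects=n_subjects,
        dose_times=FOUR_DAY_SLOTS,
        sampling={label: sched for label in treatments},
        urine_intervals={1: URINE_INTERVALS, 4: URINE_INTERVALS},
    )


def caz_avi_mtz_ddi(n_subjects: int = 28) -> CrossoverDesign:
    treatments = {
        "CAZ-AVI": (
            InfusionComponent("ceftazidime", 2000.0, 2.0),
            InfusionComponent("avibactam", 500.0, 2.0),
        ),
        "MTZ": (InfusionComponent("metronidazole", 500.0, 1.0),),
        "MTZ+CAZ-AVI": (
            InfusionComponent("metronidazole", 500.0, 1.0),
            InfusionComponent("ceftazidime", 2000.0, 2.0, offset=1.0),
            InfusionComponent("avibactam", 500.0, 2.0, offset=1.0),
        ),
    }
    sampling = {
        "CAZ-AVI": {1: CAZAVI_SCHEDULE, 4: CAZAVI_SCHEDULE},
        "MTZ": {1: MTZ_SCHEDULE, 4: MTZ_SCHEDULE},
        "MTZ+CAZ-AVI": {1: MTZ_COMBO_SCHEDULE, 4: MTZ_COMBO_SCHEDULE},
    }
    return CrossoverDesign(
        name="caz_avi_mtz_ddi",
        treatments=treatments,
        sequences=_all_orders(("CAZ-AVI", "MTZ", "MTZ+CAZ-AVI")),
        n_subjects=n_subjects,
        dose_times=FOUR_DAY_SLOTS,
        sampling=sampling,
        urine_intervals={1: URINE_INTERVALS, 4: URINE_INTERVALS},
    )


def replicate_design(
    analyte: str = "avibactam",
    amount: float = 500.0,
    duration: float = 2.0,
    n_subjects: int = 100,
    n_periods: int = 2,
    sampling: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 6.0, 8.0),
) -> CrossoverDesign:
    """Single-treatment repeated-period design for variability calibration.

    Every subject receives the same single-dose treatment in every period,
    which makes the within-subject variance of log Cmax directly estimable.
    """
    label = analyte.upper()
    return CrossoverDesign(
        name="replicate",
        treatments={label: (InfusionComponent(analyte, amount, duration),)},
        sequences=((label,) * n_periods,),
        n_subjects=n_subjects,
        dose_times=(0.0,),
        sampling={label: {1: sampling}},
    )


DESIGNS = {
    "caz_avi_pk": caz_avi_pk,
    "caz_avi_ddi": caz_avi_ddi,
    "caz_avi_mtz_ddi": caz_avi_mtz_ddi,
}


def get_design(name: str, n_subjects: int | None = None) -> CrossoverDesign:
    try:
        factory = DESIGNS[name]
    except KeyError:
        raise DesignError(
            f"unknown design {name!r}; available: {sorted(DESIGNS)}"
        ) from None
    return factory(n_subjects) if n_subjects else factory()


def default_pk_parameters() -> dict[str, PkParameters]:
    """One-compartment calibrations matching published CL and t1/2.

    V is derived from V = CL * t_half / ln 2.  Renal fractions follow the
    reported urinary recoveries (ceftazidime 91-100%, avibactam 95-100%;
    metronidazole is predominantly non-renally cleared).
    """
    import math

    def one_comp(cl: float, t_half: float, fe: float) -> PkParameters:
        return PkParameters(
            clearance=cl,
            central_volume=cl * t_half / math.log(2.0),
            renal_fraction=fe,
        )

    return {
        "ceftazidime": one_comp(7.0, 2.7, 0.95),
        "avibactam": one_comp(12.0, 2.5, 1.0),
        "metronidazole": one_comp(4.35, 8.4, 0.1),
    }


def default_within_subject_sd() -> dict[str, float]:
    """Within-subject SD of log Cmax used by the power calculation.

    0.2088 (avibactam) and 0.2171 (ceftazidime) are prior estimates; the
    metronidazole value is assumed no greater than the avibactam one.
    """
    return {"ceftazidime": 0.2171, "avibactam": 0.2088, "metronidazole": 0.2088}


def default_lloq() -> dict[str, float]:
    """Assay lower limits of quantification (ug/mL)."""
    return {"ceftazidime": 0.0446, "avibactam": 0.010, "metronidazole": 0.040}


def ddi_contrasts(design_name: str) -> tuple[tuple[str, str, str], ...]:
    """(analyte, test treatment, reference treatment) triples per design."""
    if design_name == "caz_avi_ddi":
        return (
            ("ceftazidime", "CAZ-AVI", "CAZ"),
            ("avibactam", "CAZ-AVI", "AVI"),
        )
    if design_name == "caz_avi_mtz_ddi":
        return (
            ("ceftazidime", "MTZ+CAZ-AVI", "CAZ-AVI"),
            ("avibactam", "MTZ+CAZ-AVI", "CAZ-AVI"),
            ("metronidazole", "MTZ+CAZ-AVI", "MTZ"),
        )
    raise DesignError(f"design {design_name!r} has no interaction contrasts")
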