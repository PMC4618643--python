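"""Pipeline configuration (YAML-loadable, flag-overridable)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .designs import DESIGNS, DesignError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything one end-to-end pipeline run needs.

    ``within_subject_sd``/``lloq`` override per-analyte defaults when set;
    ``zero_variability`` switches the simulator to noiseless profiles
    (useful for oracle checks).  The power block parameterises the design
    power calculation reported alongside the interaction analysis.
    """

    design: str = "caz_avi_mtz_ddi"
    seed: int = 0
    outdir: str = "crosspk_output"
    n_subjects: int | None = None
    between_subject_sd: float | None = None
    within_subject_sd: dict[str, float] | None = None
    residual_cv: float | None = None
    lloq: dict[str, float] | None = None
    zero_variability: bool = False
    tau: float = 8.0
    power_n: int = 24
    power_sigma_w: float = 0.2171
    power_limits: tuple[float, float] = (0.8, 1.25)
    power_alpha: float = 0.05
    power_reps: int = 10_000

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise DesignError(
                f"unknown design {self.design!r}; available: {sorted(DESIGNS)}"
            )
        self.power_limits = tuple(self.power_limits)  # type: ignore[assignment]
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        if self.lloq is not None and any(v <= 0 for v in self.lloq.values()):
            raise ValueError("LLOQ values must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["power_limits"] = list(self.power_limits)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
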