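"""Run configuration: one YAML-backed record consumed by every stage.

CLI flags override file values; reports embed the hash of the resolved
configuration so any output can be traced to the exact settings.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields, replace

import yaml

from .exceptions import ValidationError
from .preprocess import PreprocessConfig


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "nirsalt_out"
    # generator
    n_g1: int = 310
    n_g2: int = 60
    generator_overrides: dict = field(default_factory=dict)
    # preprocessing
    sg_window: int = 17
    sg_polyorder: int = 2
    derivative_order: int = 1
    region_low: float | None = None
    region_high: float | None = None
    # calibration
    calibration_cohort: str = "G1"
    max_components: int = 12
    parsimony_factor: float = 1.02
    outlier_rule: str = "chi2:0.999"
    scale: bool = False
    cv_scheme: str = "loo"  # "loo" or "kfold:<k>"
    # correction
    shift_threshold_factor: float = 1.5
    report_precision: int = 2

    def __post_init__(self) -> None:
        if self.n_g1 < 0 or self.n_g2 < 0:
            raise ValidationError("cohort sizes must be non-negative")
        if self.calibration_cohort not in ("G1", "G2", "G1+G2"):
            raise ValidationError(f"bad calibration_cohort {self.calibration_cohort!r}")
        if not (self.cv_scheme == "loo" or self.cv_scheme.startswith("kfold:")):
            raise ValidationError(f"bad cv_scheme {self.cv_scheme!r}")

    # -- derived views ----------------------------------------------------

    def preprocess_config(self) -> PreprocessConfig:
        region = None
        if self.region_low is not None and self.region_high is not None:
            region = (self.region_low, self.region_high)
        return PreprocessConfig(
            sg_window=self.sg_window,
            sg_polyorder=self.sg_polyorder,
            derivative_order=self.derivative_order,
            region=region,
        )

    def cv(self):
        if self.cv_scheme == "loo":
            return "loo"
        return ("kfold", int(self.cv_scheme.split(":", 1)[1]))

    # -- persistence ------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def with_overrides(self, **kw) -> "RunConfig":
        kw = {k: v for k, v in kw.items() if v is not None}
        return replace(self, **kw)

    def hash(self) -> str:
        canonical = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
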