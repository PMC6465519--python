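"""Configuration objects for the synthetic cohort generator and the pipeline.

Defaults encode the study conditions of the emulated cohort: 47 RRMS patients
and 47 sex/age-matched healthy controls, patient ages 37.69 (9.22) years in
21.5-60.2, 30 women per group, overdispersed T2 lesion counts 59.23 (46.75)
for MS vs 3.09 (3.58) for HC, lesion volumes 5.07 (6.86) ml vs 0.07 (0.09) ml,
and NAWM sT1w/T2w effects of -0.02 for MS diagnosis, -0.001 per year of age
and -0.0004 per T2 lesion around a baseline median of 0.41.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml


class InvalidConfigError(ValueError):
    """A configuration value violates its invariants."""


DEFAULT_T1W_MEANS = {"csf": 100.0, "gm": 300.0, "wm": 430.0, "lesion": 250.0}
DEFAULT_T2W_MEANS = {"csf": 120.0, "gm": 60.0, "wm": 40.0, "lesion": 90.0}

_TISSUES = ("csf", "gm", "wm", "lesion")


def _as_tuple(value: Any) -> tuple:
    return tuple(value) if isinstance(value, (list, tuple)) else value


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic two-group MRI cohort.

    Intensity means are in arbitrary scanner units; gains are per-subject
    multiplicative lognormal factors (SD of the log-gain); the bias amplitude
    is the maximum fractional deviation of the smooth multiplicative field;
    effects are slopes of the implanted NAWM sT1w/T2w median.
    """

    grid_shape: tuple = (64, 64, 64)
    voxel_size_mm: float = 2.0
    tissue_means_t1w: dict = field(default_factory=lambda: dict(DEFAULT_T1W_MEANS))
    tissue_means_t2w: dict = field(default_factory=lambda: dict(DEFAULT_T2W_MEANS))
    gain_sd_t1w: float = 0.14
    gain_sd_t2w: float = 0.14
    noise_sd: float = 2.0
    bias_amplitude: float = 0.2
    n_per_group: int = 47
    baseline_st: float = 0.41
    effect_ms: float = -0.02
    effect_age: float = -0.001
    effect_lesion_count: float = -0.0004
    lesion_count_moments: dict = field(
        default_factory=lambda: {"MS": (59.23, 46.75), "HC": (3.09, 3.58)}
    )
    lesion_volume_moments: dict = field(
        default_factory=lambda: {"MS": (5.07, 6.86), "HC": (0.07, 0.09)}
    )
    duration_moments: tuple = (24.6, 57.57)
    age_mean: float = 37.69
    age_sd: float = 9.22
    age_range: tuple = (21.5, 60.2)
    female_count: int = 30
    edss_range: tuple = (0.0, 6.0)
    head_size_mean: float = 1.25
    head_size_sd: float = 0.06
    head_size_sex_gap: float = 0.08
    missing_head_size: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        self.grid_shape = _as_tuple(self.grid_shape)
        self.age_range = _as_tuple(self.age_range)
        self.edss_range = _as_tuple(self.edss_range)
        self.duration_moments = _as_tuple(self.duration_moments)
        for attr in ("lesion_count_moments", "lesion_volume_moments"):
            d = getattr(self, attr)
            setattr(self, attr, {k: tuple(v) for k, v in d.items()})

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) < 16 for s in self.grid_shape):
            raise InvalidConfigError("grid_shape must be 3 axes, each >= 16 voxels")
        if self.voxel_size_mm <= 0:
            raise InvalidConfigError("voxel_size_mm must be positive")
        for name, means in (
            ("tissue_means_t1w", self.tissue_means_t1w),
            ("tissue_means_t2w", self.tissue_means_t2w),
        ):
            missing = set(_TISSUES) - set(means)
            if missing:
                raise InvalidConfigError(f"{name} missing tissues: {sorted(missing)}")
            if any(means[t] <= 0 for t in _TISSUES):
                raise InvalidConfigError(f"{name} must be strictly positive")
        if self.gain_sd_t1w < 0 or self.gain_sd_t2w < 0:
            raise InvalidConfigError("gain SDs must be >= 0")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        if not 0 <= self.bias_amplitude < 0.5:
            raise InvalidConfigError("bias_amplitude must lie in [0, 0.5)")
        if self.n_per_group < 1:
            raise InvalidConfigError("n_per_group must be >= 1")
        if not 0 <= self.female_count <= self.n_per_group:
            raise InvalidConfigError("female_count must lie in [0, n_per_group]")
        lo, hi = self.age_range
        if not lo < hi or self.age_sd <= 0:
            raise InvalidConfigError("age_range must be increasing and age_sd > 0")
        for group, (m, s) in self.lesion_count_moments.items():
            if m < 0 or s < 0:
                raise InvalidConfigError(f"lesion count moments for {group} must be >= 0")
            vm, _ = self.lesion_volume_moments[group]
            if m > 0 and vm <= 0:
                raise InvalidConfigError(
                    f"lesion volume mean for {group} must be > 0 when counts can be > 0"
                )
        if self.seed is not None and self.seed < 0:
            raise InvalidConfigError("seed must be a non-negative integer")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm) ** 3

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "GeneratorConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InvalidConfigError(f"unknown generator keys: {sorted(unknown)}")
        return cls(**dict(data))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunConfig:
    """Options for a full simulate → preprocess → ratio → stats run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    bias_degree: int = 2
    eps_rel: float = 1e-6
    removal_alpha: float = 0.05
    bonferroni_alpha: float = 0.004
    outdir: str | None = None
    stages: tuple = ("simulate", "preprocess", "ratio", "stats")

    def validate(self) -> None:
        self.generator.validate()
        if self.bias_degree not in (1, 2, 3):
            raise InvalidConfigError("bias_degree must be 1, 2 or 3")
        if not 0 < self.removal_alpha < 1 or not 0 < self.bonferroni_alpha < 1:
            raise InvalidConfigError("alpha levels must lie in (0, 1)")
        if self.generator.seed is None:
            raise InvalidConfigError("a seed is mandatory for a pipeline run")
        bad = set(self.stages) - {"simulate", "preprocess", "ratio", "stats"}
        if bad:
            raise InvalidConfigError(f"unknown stages: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        gen = GeneratorConfig.from_mapping(data.pop("generator", {}))
        known = {f for f in cls.__dataclass_fields__} - {"generator"}
        unknown = set(data) - known
        if unknown:
            raise InvalidConfigError(f"unknown run keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(generator=gen, **data)

    def to_yaml(self, path: str | Path) -> None:
        def plain(obj):
            if isinstance(obj, tuple):
                return [plain(v) for v in obj]
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            return obj

        data = {k: plain(v) for k, v in asdict(self).items() if k != "generator"}
        data["generator"] = plain(self.generator.to_dict())
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
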