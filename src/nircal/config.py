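"""Run configuration: one YAML-serializable object covering simulation,
model development and validation; every run writes the resolved config
beside its outputs so results are reproducible byte-for-byte."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .preprocess import METHODS, PreprocessSpec
from .synth import NoiseModel


@dataclass
class RunConfig:
    # instrument grid
    grid_start_cm1: float = 11000.0
    grid_end_cm1: float = 4000.0
    grid_step_cm1: float = 8.0
    # calibration region and pre-treatments to scan
    region: tuple[float, float] = (7500.0, 4000.0)
    pretreatments: list[str] = field(default_factory=lambda: list(METHODS))
    window_points: int = 11
    poly_order: int = 2
    gap_points: int = 5
    segment_points: int = 5
    deresolve_factor: int = 2
    # regression
    methods: tuple[str, ...] = ("pcr", "pls")
    max_factors: int = 10
    cv_scheme: str = "loo"          # "loo" or "lgo:<k>"
    selection_rule: str = "ratio"   # "ratio" or "ftest"
    f_thresh: float = 1.05
    # validation
    beta: float = 0.95
    acceptance_rel: float = 5.0
    # protocol
    n_series: int = 3
    val_levels: tuple[int, ...] = (1, 3, 5)
    val_reps: int = 4
    # simulation noise
    sigma_additive: float = NoiseModel.sigma_additive
    sigma_scatter: float = NoiseModel.sigma_scatter
    sigma_series: float = NoiseModel.sigma_series
    baseline_slope_range: float = NoiseModel.baseline_slope_range
    baseline_offset: float = NoiseModel.baseline_offset
    n_bands_per_component: int = 3
    seed: int = 0

    def noise_model(self) -> NoiseModel:
        return NoiseModel(
            sigma_additive=self.sigma_additive,
            sigma_scatter=self.sigma_scatter,
            sigma_series=self.sigma_series,
            baseline_slope_range=self.baseline_slope_range,
            baseline_offset=self.baseline_offset,
            seed=self.seed,
        )

    def preprocess_specs(self) -> list[PreprocessSpec]:
        return [
            PreprocessSpec(
                method=m,
                window_points=self.window_points,
                poly_order=self.poly_order,
                gap_points=self.gap_points,
                segment_points=self.segment_points,
                deresolve_factor=self.deresolve_factor,
                region=self.region,
            )
            for m in self.pretreatments
        ]

    def scheme(self) -> str | tuple[str, int]:
        if self.cv_scheme == "loo":
            return "loo"
        if self.cv_scheme.startswith("lgo:"):
            return ("lgo", int(self.cv_scheme.split(":", 1)[1]))
        raise ValueError(f"unknown cv_scheme {self.cv_scheme!r}")

    # -- serialization --------------------------------------------------

    def to_yaml(self) -> str:
        d = asdict(self)
        d["region"] = list(d["region"])
        d["methods"] = list(d["methods"])
        d["val_levels"] = list(d["val_levels"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        for key, caster in (("region", tuple), ("methods", tuple), ("val_levels", tuple)):
            if key in d:
                d[key] = caster(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
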