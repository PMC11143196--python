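"""Run configuration for the orchestrated pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["RunConfig", "STAGES"]

STAGES = ("simulate", "segment", "phenotype", "abundance", "spatial", "morphometry")

# stage -> stages that must run before it (or whose products must exist)
_DEPENDENCIES = {
    "phenotype": ("simulate", "segment"),  # needs a cell table from either
    "abundance": ("phenotype",),
    "spatial": ("phenotype",),
    "morphometry": ("phenotype",),
}


@dataclass
class RunConfig:
    """Everything needed for one pipeline run.

    ``mode`` selects the input: "simulate" (generate synthetic ROIs),
    "cell_table" (read an existing table) or "image" (segment a TIFF).
    """

    mode: str = "simulate"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    outdir: str = "spatialplex_out"
    # simulate-mode parameters
    groups: list[str] = field(
        default_factory=lambda: ["group1", "group2", "group3", "thrlbcl"]
    )
    cases_per_group: int = 2
    rois_per_case: int = 2
    n_cells: int = 1500
    # input paths for the other modes
    cell_table_path: str | None = None
    image_path: str | None = None
    # stage parameters
    segmentation: dict = field(default_factory=dict)
    threshold_method: str = "gmm2"
    arcsinh_cofactor: float = 150.0
    d_min: float = 3.0
    d_max: float = 30.0
    n_perm: int = 200
    floor_fraction: float = 0.001
    floor_count: int = 20

    def validate(self) -> None:
        if self.mode not in ("simulate", "cell_table", "image"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stage(s): {unknown}")
        if self.mode == "cell_table":
            if not self.cell_table_path:
                raise ConfigError("cell_table mode requires cell_table_path")
            if not Path(self.cell_table_path).exists():
                raise ConfigError(f"cell table not found: {self.cell_table_path}")
        if self.mode == "image":
            if not self.image_path:
                raise ConfigError("image mode requires image_path")
            if not Path(self.image_path).exists():
                raise ConfigError(f"image not found: {self.image_path}")
        enabled = set(self.stages)
        if self.mode != "simulate":
            enabled.discard("simulate")
        if self.mode != "image":
            enabled.discard("segment")
        for stage in self.stages:
            deps = _DEPENDENCIES.get(stage, ())
            if deps and not any(d in enabled for d in deps):
                # cell_table mode satisfies the phenotype input dependency
                if stage == "phenotype" and self.mode == "cell_table":
                    continue
                if "phenotype" in deps and "phenotype" in enabled:
                    continue
                raise ConfigError(
                    f"stage {stage!r} requires one of {deps} to be enabled"
                )
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if not (0 <= self.d_min < self.d_max):
            raise ConfigError("need 0 <= d_min < d_max")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**payload)
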