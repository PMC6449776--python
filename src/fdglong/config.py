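"""Pipeline configuration with the study's default analysis settings.

Defaults reproduce the emulated study's stated processing parameters:
8 mm FWHM PSF, Van Cittert step length 1.5 with a 1% stopping rule,
cluster-forming p < .001 with cluster-level alpha 0.05, cerebellum
reference, and the 0-84 month scan schedule.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .phantom import DEFAULT_SCAN_MONTHS

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # phantom cohort
    grid_shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    n_regions: int = 25
    n_per_group: int = 24
    scan_months: tuple[int, ...] = DEFAULT_SCAN_MONTHS
    noise_sd: float = 0.02
    subject_intercept_sd: float = 0.09
    atrophy: dict[str, float] = field(default_factory=dict)
    # partial volume correction
    psf_fwhm_mm: float = 8.0
    alpha: float = 1.5
    tol_percent: float = 1.0
    max_iter: int = 30
    apply_pvc: bool = True
    compare_non_pvc: bool = True
    # SUVR / models
    reference_region: str = "cerebellum"
    random_slope: bool = False
    roi_alpha: float = 0.05
    # voxelwise inference
    cft_p: float = 0.001
    cluster_alpha: float = 0.05
    n_permutations: int = 500
    followup_month: int = 72
    # survival
    fh_weight_p: float = 1.0
    fh_weight_q: float = 0.0
    # bookkeeping
    seed: int = 0
    out_dir: str = "runs"

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.scan_months = tuple(int(m) for m in self.scan_months)
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be a triple of sizes >= 4, got {self.grid_shape}")
        if not 0 < self.alpha < 2:
            raise ValueError(f"alpha must be in (0, 2), got {self.alpha}")
        if self.tol_percent <= 0 or self.max_iter < 1:
            raise ValueError("tol_percent must be > 0 and max_iter >= 1")
        if self.psf_fwhm_mm < 0 or self.noise_sd < 0:
            raise ValueError("psf_fwhm_mm and noise_sd must be non-negative")
        if not 0 < self.cft_p <= 0.5:
            raise ValueError(f"cft_p must be in (0, 0.5], got {self.cft_p}")
        if not 0 < self.cluster_alpha < 1 or not 0 < self.roi_alpha < 1:
            raise ValueError("significance levels must be in (0, 1)")
        if self.n_permutations < 1 or self.n_per_group < 2 or self.n_regions < 2:
            raise ValueError("n_permutations >= 1, n_per_group >= 2, n_regions >= 2 required")
        if self.followup_month not in self.scan_months:
            raise ValueError(
                f"followup_month {self.followup_month} not in scan schedule {self.scan_months}"
            )
        if self.scan_months[0] != 0:
            raise ValueError("scan_months must start at 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["voxel_size_mm"] = list(self.voxel_size_mm)
        d["scan_months"] = list(self.scan_months)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)
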