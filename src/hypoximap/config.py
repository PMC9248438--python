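"""Configuration models for the phantom, the fits and the ROI analysis.

Defaults encode the study conditions: protocol geometry, tissue-wise
parameter means/SDs for diffusion (D), pseudo-diffusion (D*), perfusion
fraction (f), relaxation rate (R2*) and the HIF-1a score, plus the
rank-coupling between the HIF field and the R2*/D* fields.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .protocol import AcquisitionProtocol


class TissueParams(BaseModel):
    """Per-tissue means and SDs of the quantitative parameters.

    Units: D and D* in mm²/s, f as a fraction in [0, 1], R2* in Hz,
    HIF on the 0-300 score scale.
    """

    d_mean: float = Field(gt=0)
    d_sd: float = Field(ge=0)
    dstar_mean: float = Field(gt=0)
    dstar_sd: float = Field(ge=0)
    f_mean: float = Field(ge=0, le=1)
    f_sd: float = Field(ge=0)
    r2star_mean: float = Field(gt=0)
    r2star_sd: float = Field(ge=0)
    hif_mean: float = Field(gt=0, le=300)
    hif_sd: float = Field(gt=0)


#: Contralateral normal brain defaults.
NORMAL_TISSUE = TissueParams(
    d_mean=414.21e-6, d_sd=53.38e-6,
    dstar_mean=2755.02e-6, dstar_sd=441.42e-6,
    f_mean=0.4629, f_sd=0.0275,
    r2star_mean=36.74, r2star_sd=9.35,
    hif_mean=21.13, hif_sd=19.14,
)

#: Glioma tissue defaults.
TUMOR_TISSUE = TissueParams(
    d_mean=419.50e-6, d_sd=81.97e-6,
    dstar_mean=2850.23e-6, dstar_sd=444.48e-6,
    f_mean=0.5109, f_sd=0.0858,
    r2star_mean=38.24, r2star_sd=8.76,
    hif_mean=123.73, hif_sd=70.18,
)


class PhantomConfig(BaseModel):
    """Digital rat-head phantom: geometry, tissue statistics, couplings.

    The brain is an ellipsoid centred in the volume; the tumor is a
    radius-perturbed sphere offset into one basal-ganglia hemisphere.
    Couplings are latent-Gaussian correlations between the HIF field
    and the R2* (positive) / D* (negative) fields.
    """

    shape: tuple[int, int, int] = (96, 96, 12)
    voxel_size_mm: tuple[float, float, float] = (25.6 / 96, 25.6 / 96, 1.0)
    brain_semiaxes_mm: tuple[float, float, float] = (9.5, 7.4, 6.0)
    tumor_center_offset_mm: tuple[float, float, float] = (-2.6, 0.0, 0.0)
    tumor_volume_mm3: float = Field(default=458.0, gt=0)
    radius_perturbation: float = Field(default=0.04, ge=0, lt=0.5)
    perturbation_smooth_mm: float = Field(default=1.0, gt=0)
    vessel_fraction: float = Field(default=0.04, ge=0, le=1)
    necrosis_fraction: float = Field(default=0.06, ge=0, le=1)
    calcification_fraction: float = Field(default=0.01, ge=0, le=1)
    noise_sigma: float = Field(default=0.01, ge=0)  # fraction of normal-brain S0
    coupling_r2star: float = Field(default=0.43, ge=-1, le=1)
    coupling_dstar: float = Field(default=-0.30, ge=-1, le=1)
    hif_core_rim_gradient: float = Field(default=1.05, ge=0)
    dstar_core_rim_gradient: float = -0.21
    f_core_rim_gradient: float = -0.13
    latent_smooth_mm: float = Field(default=0.6, ge=0)
    cell_density_per_mm2: float = Field(default=1000.0, gt=0)
    normal: TissueParams = NORMAL_TISSUE
    tumor: TissueParams = TUMOR_TISSUE
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PhantomConfig":
        if self.vessel_fraction + self.necrosis_fraction + self.calcification_fraction > 1:
            raise ValueError("intratumoral component fractions must sum to <= 1")
        if self.coupling_r2star**2 + self.coupling_dstar**2 > 1:
            raise ValueError("coupling coefficients must satisfy a^2 + b^2 <= 1")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel size must be positive")
        return self

    @property
    def tumor_radius_mm(self) -> float:
        """Sphere-equivalent tumor radius for the requested volume."""
        return (3.0 * self.tumor_volume_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)


class FitConfig(BaseModel):
    """IVIM fitting configuration (segmented and full fits)."""

    high_b_threshold: float = Field(default=200.0, gt=0)  # exclusive
    d_bounds: tuple[float, float] = (1e-6, 4e-3)
    dstar_max: float = 0.1
    f_bounds: tuple[float, float] = (0.0, 1.0)
    max_iter: int = Field(default=80, ge=1)
    tol: float = Field(default=1e-10, gt=0)
    refine: bool = True  # iterate the perfusion-subtraction correction

    @model_validator(mode="after")
    def _check(self) -> "FitConfig":
        if self.d_bounds[0] <= 0 or self.d_bounds[1] <= self.d_bounds[0]:
            raise ValueError("invalid D bounds")
        if self.dstar_max <= self.d_bounds[0]:
            raise ValueError("D* upper bound must exceed the D lower bound")
        return self


class R2StarFitConfig(BaseModel):
    """R2* fitting configuration."""

    r2_bounds: tuple[float, float] = (0.1, 2000.0)  # Hz
    noise_sigma: float | None = None  # absolute; echoes below 2*sigma dropped
    noise_floor_factor: float = 2.0
    refine: bool = True
    min_echoes: int = 3


class AnalysisConfig(BaseModel):
    """Grid tessellation and ROI inclusion rules."""

    roi_side_mm: float = Field(default=1.0, gt=0)
    composition_threshold: float = Field(default=0.25, gt=0, le=1)
    edge_distance_mm: float = Field(default=1.0, gt=0)
    hif_cut: float = Field(default=150.0, gt=0)
    normal_roi_policy: Literal["contralateral", "all"] = "contralateral"


class StudyConfig(BaseModel):
    """One end-to-end synthetic study: a pooled cohort of phantoms."""

    n_animals: int = Field(default=6, ge=1)
    tumor_volume_sd_mm3: float = Field(default=46.52, ge=0)
    phantom: PhantomConfig = PhantomConfig()
    protocol: AcquisitionProtocol = AcquisitionProtocol()
    ivim: FitConfig = FitConfig()
    r2star: R2StarFitConfig = R2StarFitConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    ivim_method: Literal["segmented", "full"] = "segmented"
    write_volumes: bool = True
    seed: int = 0


def load_config(path: str | Path) -> StudyConfig:
    """Load a study configuration from a YAML or JSON document."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return StudyConfig.model_validate(data or {})


def config_hash(cfg: BaseModel) -> str:
    """Stable sha256 of a config's canonical JSON form."""
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()
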