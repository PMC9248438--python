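"""Digital glioma phantom: labels, truth maps, MR signal and cell tables.

The generator emulates a rat head with a basal-ganglia tumor on the
acquisition grid of the protocol.  Every output is a pure function of
(config, seed): each stage draws from its own substream derived from
the master seed, so stages can be re-run independently and still
reproduce bit-identically.

Tissue label codes
------------------
0 background (air), 1 normal brain, 2 tumor, 3 vessel, 4 necrosis,
5 calcification.  Codes 3-5 occur only inside the tumor extent.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtr
from scipy.stats import gamma as gamma_dist

from .config import PhantomConfig, TissueParams

BACKGROUND, NORMAL, TUMOR, VESSEL, NECROSIS, CALCIFICATION = range(6)

#: Codes counted as tumor tissue for the purity rule.
TUMOR_CODES = (TUMOR, VESSEL, NECROSIS, CALCIFICATION)

#: Codes counted against the 25% intratumoral-composition rule.
COMPONENT_CODES = (VESSEL, NECROSIS, CALCIFICATION)

LABEL_NAMES = {
    BACKGROUND: "background", NORMAL: "normal", TUMOR: "tumor",
    VESSEL: "vessel", NECROSIS: "necrosis", CALCIFICATION: "calcification",
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random substream of a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    )


@dataclass
class TissueLabelVolume:
    """Integer-coded 3D tissue map on a physical grid."""

    labels: np.ndarray  # (nx, ny, nz) int8
    voxel_size_mm: tuple[float, float, float]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def tumor_mask(self) -> np.ndarray:
        return np.isin(self.labels, TUMOR_CODES)

    def tumor_volume_mm3(self) -> float:
        return float(self.tumor_mask().sum()) * self.voxel_volume_mm3


@dataclass
class TruthMaps:
    """Per-voxel ground-truth quantitative parameter fields.

    D, D* in mm²/s, f dimensionless in [0,1], R2* in Hz, HIF on the
    0-300 score scale; S0 is the unit-free equilibrium signal.
    """

    d: np.ndarray
    dstar: np.ndarray
    f: np.ndarray
    r2star: np.ndarray
    hif: np.ndarray
    s0: np.ndarray
    voxel_size_mm: tuple[float, float, float]


@dataclass
class DwiSeries:
    """4D diffusion-weighted magnitude stack, last axis indexed by b."""

    data: np.ndarray  # (nx, ny, nz, nb)
    b_values: tuple[float, ...]
    voxel_size_mm: tuple[float, float, float]
    sigma: float = 0.0


@dataclass
class MegeSeries:
    """4D multi-echo gradient-echo magnitude stack, last axis by TE."""

    data: np.ndarray  # (nx, ny, nz, nte)
    echo_times_s: tuple[float, ...]
    voxel_size_mm: tuple[float, float, float]
    sigma: float = 0.0


def _grid_coords(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Physical voxel-center coordinates relative to the volume center."""
    axes = []
    for n, dv in zip(config.shape, config.voxel_size_mm):
        axes.append((np.arange(n) + 0.5) * dv - n * dv / 2.0)
    return np.meshgrid(*axes, indexing="ij")


def _smooth_unit_field(shape: tuple[int, ...], sigma_vox,
                       rng: np.random.Generator) -> np.ndarray:
    """Smoothed white noise re-standardized to zero mean, unit SD."""
    field_ = rng.standard_normal(shape)
    if np.any(np.asarray(sigma_vox) > 0):
        field_ = ndimage.gaussian_filter(field_, sigma=sigma_vox)
    field_ -= field_.mean()
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def generate_label_volume(config: PhantomConfig) -> TissueLabelVolume:
    """Build the tissue label volume for one phantom animal.

    The brain is an ellipsoid; the tumor is a sphere whose radius is
    modulated by a seeded smooth random field (lobulated margin).
    Intratumoral components are placed with exact voxel counts:
    necrosis as a central core (innermost voxels), vessels and
    calcifications scattered through the remaining tumor.

    Raises
    ------
    ValueError
        If the perturbed tumor is not fully contained in the brain.
    """
    rng = stage_rng(config.seed, "labels")
    x, y, z = _grid_coords(config)
    ax, ay, az = config.brain_semiaxes_mm
    brain = (x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2 <= 1.0

    cx, cy, cz = config.tumor_center_offset_mm
    dist = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
    sigma_vox = tuple(config.perturbation_smooth_mm / v for v in config.voxel_size_mm)
    bump = np.clip(_smooth_unit_field(config.shape, sigma_vox, rng), -2.0, 2.0)
    # effective radius per voxel; the threshold is chosen so the voxel
    # count reproduces the requested volume (up to one voxel)
    r_eff = dist / np.maximum(1.0 + config.radius_perturbation * bump, 0.1)
    n_target = max(1, round(config.tumor_volume_mm3 / float(np.prod(config.voxel_size_mm))))
    flat = np.sort(r_eff.ravel())
    r_thresh = flat[min(n_target, flat.size) - 1]
    if r_thresh > 1.75 * config.tumor_radius_mm:
        raise ValueError("requested tumor volume incompatible with geometry")
    tumor = r_eff <= r_thresh
    if np.any(tumor & ~brain):
        raise ValueError("tumor extends outside the brain; adjust geometry")

    labels = np.zeros(config.shape, dtype=np.int8)
    labels[brain] = NORMAL
    labels[tumor] = TUMOR

    n_tumor = int(tumor.sum())
    if n_tumor == 0:
        raise ValueError("tumor contains no voxels")
    n_nec = round(config.necrosis_fraction * n_tumor)
    n_ves = round(config.vessel_fraction * n_tumor)
    n_cal = round(config.calcification_fraction * n_tumor)

    # necrotic core: innermost voxels by normalized radial distance
    tumor_idx = np.flatnonzero(tumor.ravel())
    rel_dist = (r_eff / r_thresh).ravel()[tumor_idx]
    order = np.argsort(rel_dist, kind="stable")
    nec_idx = tumor_idx[order[:n_nec]]
    labels.ravel()[nec_idx] = NECROSIS

    remaining = tumor_idx[order[n_nec:]]
    pick = rng.permutation(remaining.size)
    labels.ravel()[remaining[pick[:n_ves]]] = VESSEL
    labels.ravel()[remaining[pick[n_ves:n_ves + n_cal]]] = CALCIFICATION

    return TissueLabelVolume(labels=labels, voxel_size_mm=config.voxel_size_mm)


def _gamma_from_moments(mean: float, sd: float):
    """Gamma distribution parameterized by mean and SD (shape, scale)."""
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return shape, scale


def generate_truth_maps(labels: TissueLabelVolume, config: PhantomConfig) -> TruthMaps:
    """Draw per-voxel ground-truth parameter fields.

    D, D*, f and R2* are tissue-wise Gaussian fields (clipped to their
    physical ranges, with D* >= D enforced).  The HIF field is a
    monotone gamma-quantile transform of a latent Gaussian that shares
    the R2* latent with a positive weight and the D* latent with a
    negative weight, so population rank correlations carry the
    configured signs.  Inside the tumor the HIF field is additionally
    scaled by a linear core-to-rim gradient with volume-mean one.
    """
    if labels.labels.shape != config.shape:
        raise ValueError("labels and config are on different grids")
    a, b = config.coupling_r2star, config.coupling_dstar
    if a**2 + b**2 > 1:
        raise ValueError("coupling coefficients must satisfy a^2 + b^2 <= 1")
    rng = stage_rng(config.seed, "truth")
    shape = config.shape
    z_r, z_d, z_f, z_dd, z_h = (rng.standard_normal(shape) for _ in range(5))
    if config.latent_smooth_mm > 0:
        sigma_vox = tuple(config.latent_smooth_mm / v for v in config.voxel_size_mm)
        z_r, z_d, z_f, z_dd, z_h = (
            _smooth_unit_field_from(zi, sigma_vox) for zi in (z_r, z_d, z_f, z_dd, z_h)
        )

    lab = labels.labels
    normal_mask = lab == NORMAL
    tumor_mask = np.isin(lab, TUMOR_CODES)
    tissue = normal_mask | tumor_mask

    d = np.zeros(shape)
    dstar = np.zeros(shape)
    f = np.zeros(shape)
    r2s = np.zeros(shape)
    hif = np.zeros(shape)

    z_hif = a * z_r + b * z_d + np.sqrt(max(0.0, 1.0 - a**2 - b**2)) * z_h
    u = np.clip(ndtr(z_hif), 1e-12, 1.0 - 1e-12)

    for mask, par in ((normal_mask, config.normal), (tumor_mask, config.tumor)):
        par: TissueParams
        d[mask] = par.d_mean + par.d_sd * z_dd[mask]
        dstar[mask] = par.dstar_mean + par.dstar_sd * z_d[mask]
        f[mask] = par.f_mean + par.f_sd * z_f[mask]
        r2s[mask] = par.r2star_mean + par.r2star_sd * z_r[mask]
        shape_g, scale_g = _gamma_from_moments(par.hif_mean, par.hif_sd)
        hif[mask] = gamma_dist.ppf(u[mask], a=shape_g, scale=scale_g)

    # core-to-rim gradients, monotone per voxel and mean-one over the
    # tumor: HIF rises toward the core while D* and f fall, mirroring
    # the spatial distribution of intratumoral perfusion
    if tumor_mask.any():
        x, y, z = _grid_coords(config)
        cx, cy, cz = config.tumor_center_offset_mm
        dist = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
        rnorm = dist / config.tumor_radius_mm
        rbar = rnorm[tumor_mask].mean()
        centrality = rbar - rnorm[tumor_mask]  # positive in the core
        for grad, arr in ((config.hif_core_rim_gradient, hif),
                          (config.dstar_core_rim_gradient, dstar),
                          (config.f_core_rim_gradient, f)):
            if grad != 0:
                arr[tumor_mask] *= np.clip(1.0 + grad * centrality, 0.0, None)

    np.clip(hif, 0.0, 300.0, out=hif)
    d[tissue] = np.clip(d[tissue], 1e-6, None)
    dstar = np.maximum(dstar, d * (1.0 + 1e-9))
    dstar[~tissue] = 0.0
    np.clip(f, 0.0, 1.0, out=f)
    r2s[tissue] = np.clip(r2s[tissue], 0.1, None)

    s0 = np.where(tissue, 1.0, 0.0)
    return TruthMaps(d=d, dstar=dstar, f=f, r2star=r2s, hif=hif, s0=s0,
                     voxel_size_mm=config.voxel_size_mm)


def _kernel_interior_sd(shape: tuple[int, ...], sigma_vox) -> float:
    """SD of Gaussian-smoothed unit white noise away from edges.

    Exact for the discrete kernel: the variance is the sum of squared
    impulse-response coefficients, probed with a centered delta.
    """
    delta = np.zeros(shape)
    delta[tuple(n // 2 for n in shape)] = 1.0
    resp = ndimage.gaussian_filter(delta, sigma=sigma_vox)
    return float(np.sqrt((resp**2).sum()))


def _smooth_unit_field_from(field_: np.ndarray, sigma_vox) -> np.ndarray:
    """Smooth white noise, rescaled so the interior keeps unit variance.

    Normalizing by the interior kernel norm (not the empirical global
    SD) avoids biasing tissue-region variances low: with reflective
    padding, edge voxels of a smoothed field run hot and would inflate
    a global SD estimate.
    """
    out = ndimage.gaussian_filter(field_, sigma=sigma_vox)
    return out / _kernel_interior_sd(field_.shape, sigma_vox)


def add_rician_noise(signal: np.ndarray, sigma: float,
                     rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Apply Rician noise to a magnitude signal.

    output = sqrt((s + g1)^2 + g2^2) with g1, g2 ~ N(0, sigma).
    sigma = 0 returns the input unchanged (a copy).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    g1 = rng.normal(0.0, sigma, size=signal.shape)
    g2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + g1) ** 2 + g2**2)


def synthesize_dwi(truth: TruthMaps, b_values: tuple[float, ...],
                   sigma: float, seed: int) -> DwiSeries:
    """Synthesize the multi-b diffusion series from the truth maps.

    Noiseless voxel signal is S0 * [(1-f) e^{-bD} + f e^{-bD*}]; Rician
    noise with the given absolute sigma is applied when sigma > 0.
    """
    b = np.asarray(b_values, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    if not np.any(b == 0):
        raise ValueError("a b=0 volume is required")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    bb = b[None, None, None, :]
    decay = ((1.0 - truth.f)[..., None] * np.exp(-bb * truth.d[..., None])
             + truth.f[..., None] * np.exp(-bb * truth.dstar[..., None]))
    data = truth.s0[..., None] * decay
    if sigma > 0:
        data = add_rician_noise(data, sigma, stage_rng(seed, "dwi-noise"))
    return DwiSeries(data=data, b_values=tuple(float(v) for v in b),
                     voxel_size_mm=truth.voxel_size_mm, sigma=sigma)


def synthesize_mege(truth: TruthMaps, echo_times_s: tuple[float, ...],
                    sigma: float, seed: int) -> MegeSeries:
    """Synthesize the multi-echo gradient-echo series: S0 e^{-TE R2*}."""
    te = np.asarray(echo_times_s, dtype=float)
    if np.any(te <= 0) or np.any(np.diff(te) <= 0):
        raise ValueError("echo times must be positive and strictly increasing")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    data = truth.s0[..., None] * np.exp(-te[None, None, None, :]
                                        * truth.r2star[..., None])
    if sigma > 0:
        data = add_rician_noise(data, sigma, stage_rng(seed, "mege-noise"))
    return MegeSeries(data=data, echo_times_s=tuple(float(v) for v in te),
                      voxel_size_mm=truth.voxel_size_mm, sigma=sigma)


def _intensity_categories(local_hif: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Draw per-cell stain categories so E[ROI score] = local HIF density.

    With s = h/300 the cell model uses positive probability p and mean
    positive category m with 100*p*m = h: for s <= 1/3 all positive
    cells are 1+ and p = 3s; above that every cell is positive and the
    category distribution mixes adjacent grades to reach mean 3s.
    """
    s = np.clip(local_hif / 300.0, 0.0, 1.0)
    n = s.size
    cat = np.zeros(n, dtype=np.int8)
    u_pos = rng.random(n)
    u_cat = rng.random(n)

    low = s <= 1.0 / 3.0
    pos_low = low & (u_pos < 3.0 * s)
    cat[pos_low] = 1

    high = ~low
    m = 3.0 * s  # mean target category in (1, 3]
    mid = high & (m <= 2.0)
    cat[mid] = 1 + (u_cat[mid] < (m[mid] - 1.0))
    top = high & (m > 2.0)
    cat[top] = 2 + (u_cat[top] < (m[top] - 2.0))
    return cat


def synthesize_cell_table(truth: TruthMaps, labels: TissueLabelVolume,
                          slice_index: int, density_per_mm2: float,
                          seed: int) -> pd.DataFrame:
    """Place IHC cells on one slice by a seeded Poisson point process.

    Cells land uniformly in tissue (any non-background voxel); each
    cell's intensity category (0-3) is drawn so that the expected ROI
    score equals the local HIF density of the containing voxel.

    Returns a DataFrame with columns x_mm, y_mm, slice, intensity.
    """
    if density_per_mm2 <= 0:
        raise ValueError("cell density must be positive")
    if density_per_mm2 < 20:
        warnings.warn("cell density below 20/mm²: 1 mm² ROI scores will be "
                      "unstable", stacklevel=2)
    rng = stage_rng(seed, f"cells-{slice_index}")
    dx, dy, _ = labels.voxel_size_mm
    lab2d = labels.labels[:, :, slice_index]
    tissue = lab2d >= NORMAL
    idx = np.argwhere(tissue)
    if idx.size == 0:
        raise ValueError("slice contains no tissue")
    area = idx.shape[0] * dx * dy
    n = rng.poisson(density_per_mm2 * area)
    pick = rng.integers(0, idx.shape[0], size=n)
    ij = idx[pick]
    x = (ij[:, 0] + rng.random(n)) * dx
    y = (ij[:, 1] + rng.random(n)) * dy
    local_hif = truth.hif[ij[:, 0], ij[:, 1], slice_index]
    cat = _intensity_categories(local_hif, rng)
    df = pd.DataFrame({
        "x_mm": x, "y_mm": y,
        "slice": np.full(n, slice_index, dtype=int),
        "intensity": cat.astype(int),
    })
    df.attrs["seed"] = seed
    df.attrs["density_per_mm2"] = density_per_mm2
    return df
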