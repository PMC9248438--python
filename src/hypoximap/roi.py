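"""1 mm² ROI grid analysis on the largest tumor slice.

The analysis slice is tessellated into axis-aligned square ROIs
anchored at the image origin; only cells lying entirely inside the
field of view are kept, so every ROI has exactly the configured area.
Voxels belong to the ROI containing their center.  Inclusion rules:

* no air (background voxels) inside the ROI;
* tissue must be exclusively tumor (intratumoral vessel, necrosis and
  calcification count as tumor tissue here) or exclusively normal;
* the combined vessel + necrosis + calcification fraction must be
  below the composition threshold (default 25%).

Included tumor ROIs whose center lies strictly within 1 mm of the
tumor boundary are peripheral, the rest central; normal ROIs keep the
region class "normal".  Histology cells share the MR frame by default;
an optional rigid transform (theta, tx, ty) maps histology coordinates
into the MR frame before cells are binned into ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .config import AnalysisConfig
from .hif import score_roi
from .phantom import BACKGROUND, COMPONENT_CODES, NORMAL, TUMOR_CODES, TissueLabelVolume

EXCLUSION_ORDER = ("air", "mixed", "composition")


def select_largest_tumor_slice(labels: TissueLabelVolume) -> int:
    """Index of the slice with the most tumor pixels (ties: lowest)."""
    counts = labels.tumor_mask().sum(axis=(0, 1))
    if counts.sum() == 0:
        raise ValueError("label volume contains no tumor")
    return int(np.argmax(counts))


@dataclass
class RoiGrid:
    """Tessellation of one slice into complete square ROIs."""

    roi_side_mm: float
    n_x: int
    n_y: int
    assignment: np.ndarray   # (nx, ny) int, cell index or -1
    centers_mm: np.ndarray   # (n_cells, 2)
    voxel_size_mm: tuple[float, float]

    @property
    def n_cells(self) -> int:
        return self.n_x * self.n_y

    def cell_of_points(self, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
        """ROI index for arbitrary in-plane points (-1 if off-grid)."""
        ix = np.floor(np.asarray(x_mm) / self.roi_side_mm).astype(int)
        iy = np.floor(np.asarray(y_mm) / self.roi_side_mm).astype(int)
        ok = (ix >= 0) & (ix < self.n_x) & (iy >= 0) & (iy < self.n_y)
        return np.where(ok, ix * self.n_y + iy, -1)


def tessellate(shape2d: tuple[int, int], voxel_size_mm: tuple[float, float],
               roi_side_mm: float = 1.0) -> RoiGrid:
    """Grid the slice into half-open squares [k*s, (k+1)*s) anchored at 0.

    Cells extending past the field of view are dropped; each voxel
    center falls in exactly one retained or dropped cell, so retained
    cells partition the interior.
    """
    dx, dy = voxel_size_mm
    if roi_side_mm < max(dx, dy):
        raise ValueError("ROI side must be at least one voxel")
    nx, ny = shape2d
    ext_x, ext_y = nx * dx, ny * dy
    n_x = int(np.floor(ext_x / roi_side_mm + 1e-9))
    n_y = int(np.floor(ext_y / roi_side_mm + 1e-9))
    cx = (np.arange(nx) + 0.5) * dx
    cy = (np.arange(ny) + 0.5) * dy
    ix = np.floor(cx / roi_side_mm).astype(int)
    iy = np.floor(cy / roi_side_mm).astype(int)
    assign = np.full((nx, ny), -1, dtype=int)
    okx = ix < n_x
    oky = iy < n_y
    assign[np.ix_(okx, oky)] = ix[okx, None] * n_y + iy[None, oky]
    gx, gy = np.meshgrid(np.arange(n_x), np.arange(n_y), indexing="ij")
    centers = np.stack([(gx.ravel() + 0.5) * roi_side_mm,
                        (gy.ravel() + 0.5) * roi_side_mm], axis=1)
    return RoiGrid(roi_side_mm=roi_side_mm, n_x=n_x, n_y=n_y,
                   assignment=assign, centers_mm=centers,
                   voxel_size_mm=(dx, dy))


def compute_composition(grid: RoiGrid, labels2d: np.ndarray) -> np.ndarray:
    """Per-ROI label-code fractions, shape (n_cells, 6); rows sum to 1."""
    flat_assign = grid.assignment.ravel()
    flat_lab = labels2d.ravel()
    inside = flat_assign >= 0
    counts = np.zeros((grid.n_cells, 6))
    np.add.at(counts, (flat_assign[inside], flat_lab[inside]), 1.0)
    totals = counts.sum(axis=1, keepdims=True)
    return counts / np.maximum(totals, 1.0)


def tumor_boundary_mask(tumor2d: np.ndarray) -> np.ndarray:
    """Tumor pixels with at least one non-tumor 4-neighbour."""
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    eroded = ndimage.binary_erosion(tumor2d, structure=structure,
                                    border_value=0)
    return tumor2d & ~eroded


def classify_region(centers_mm: np.ndarray, tumor2d: np.ndarray,
                    voxel_size_mm: tuple[float, float],
                    edge_distance_mm: float = 1.0) -> np.ndarray:
    """central/peripheral call for tumor-ROI centers.

    Distance is in-plane Euclidean from the ROI center to the nearest
    tumor-boundary pixel center; strictly less than the edge distance
    means peripheral.
    """
    if not tumor2d.any():
        raise ValueError("tumor mask is empty")
    boundary = np.argwhere(tumor_boundary_mask(tumor2d)).astype(float)
    dx, dy = voxel_size_mm
    boundary_mm = (boundary + 0.5) * np.array([dx, dy])
    tree = cKDTree(boundary_mm)
    dist, _ = tree.query(centers_mm)
    return np.where(dist < edge_distance_mm, "peripheral", "central")


def _tissue_class(comp: np.ndarray) -> np.ndarray:
    """tumor / normal / excluded(mixed) per ROI from composition rows."""
    tumor_frac = comp[:, list(TUMOR_CODES)].sum(axis=1)
    normal_frac = comp[:, NORMAL]
    air_frac = comp[:, BACKGROUND]
    tissue_total = tumor_frac + normal_frac
    cls = np.full(comp.shape[0], "mixed", dtype=object)
    with np.errstate(invalid="ignore"):
        pure_tumor = (tumor_frac > 0) & np.isclose(tumor_frac + air_frac, 1.0)
        pure_normal = (normal_frac > 0) & np.isclose(normal_frac + air_frac, 1.0)
    cls[pure_tumor] = "tumor"
    cls[pure_normal] = "normal"
    cls[tissue_total == 0] = "empty"
    return cls


def build_roi_table(labels2d: np.ndarray, grid: RoiGrid,
                    cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Classify every complete grid cell: tissue class, filters, region.

    Returns one row per grid cell (a partition) with columns: roi_id,
    grid indices, center coordinates, composition fractions comp_0..5,
    tissue_class, included, exclusion_reason ("" when included) and
    region_class (central | peripheral | normal | "").
    """
    cfg = cfg or AnalysisConfig()
    comp = compute_composition(grid, labels2d)
    n = grid.n_cells
    n_vox = np.zeros(n)
    flat_assign = grid.assignment.ravel()
    inside = flat_assign >= 0
    np.add.at(n_vox, flat_assign[inside], 1.0)

    tissue = _tissue_class(comp)
    component_frac = comp[:, list(COMPONENT_CODES)].sum(axis=1)
    air_frac = comp[:, BACKGROUND]

    reason = np.full(n, "", dtype=object)
    # fixed precedence: air -> mixed -> composition
    empty = (tissue == "empty") | (n_vox == 0)
    reason[empty] = "empty"
    has_air = (air_frac > 0) & ~empty
    reason[has_air] = "air"
    is_mixed = (tissue == "mixed") & (reason == "")
    reason[is_mixed] = "mixed"
    over = (component_frac >= cfg.composition_threshold) & (reason == "")
    reason[over] = "composition"
    included = reason == ""

    region = np.full(n, "", dtype=object)
    tumor2d = np.isin(labels2d, TUMOR_CODES)
    tumor_roi = included & (tissue == "tumor")
    if tumor_roi.any():
        region[tumor_roi] = classify_region(
            grid.centers_mm[tumor_roi], tumor2d, grid.voxel_size_mm,
            cfg.edge_distance_mm)
    region[included & (tissue == "normal")] = "normal"

    gi, gj = np.divmod(np.arange(n), grid.n_y)
    df = pd.DataFrame({
        "roi_id": np.arange(n), "grid_i": gi, "grid_j": gj,
        "center_x_mm": grid.centers_mm[:, 0],
        "center_y_mm": grid.centers_mm[:, 1],
        "n_voxels": n_vox.astype(int),
        "tissue_class": tissue,
        "included": included,
        "exclusion_reason": reason,
        "region_class": region,
    })
    for code in range(6):
        df[f"comp_{code}"] = comp[:, code]
    return df


def apply_rigid(x_mm: np.ndarray, y_mm: np.ndarray,
                transform: tuple[float, float, float] | None,
                center_mm: tuple[float, float] = (0.0, 0.0)
                ) -> tuple[np.ndarray, np.ndarray]:
    """Rigid histology -> MR mapping: rotate by theta about a center,
    then translate by (tx, ty).  ``transform=None`` is the identity."""
    if transform is None:
        return np.asarray(x_mm, float), np.asarray(y_mm, float)
    theta, tx, ty = transform
    cx, cy = center_mm
    c, s = np.cos(theta), np.sin(theta)
    xr = cx + c * (x_mm - cx) - s * (y_mm - cy) + tx
    yr = cy + s * (x_mm - cx) + c * (y_mm - cy) + ty
    return xr, yr


def aggregate_roi(roi_table: pd.DataFrame, grid: RoiGrid,
                  param_maps: dict[str, np.ndarray],
                  converged: dict[str, np.ndarray],
                  cells: pd.DataFrame,
                  cfg: AnalysisConfig | None = None,
                  transform: tuple[float, float, float] | None = None,
                  truth_maps: dict[str, np.ndarray] | None = None
                  ) -> pd.DataFrame:
    """Attach per-ROI imaging means and HIF scores to the ROI table.

    Imaging means are arithmetic means over the ROI's converged voxels;
    ROIs with zero converged voxels for any parameter, or with no
    cells, are re-excluded with reason "empty".  ``truth_maps`` adds
    ground-truth columns (means over all ROI voxels) for validation.
    """
    cfg = cfg or AnalysisConfig()
    df = roi_table.copy()
    n = grid.n_cells
    flat_assign = grid.assignment.ravel()
    inside = flat_assign >= 0
    idx = flat_assign[inside]

    for name, pmap in param_maps.items():
        if pmap.shape != grid.assignment.shape:
            raise ValueError(f"parameter map '{name}' is not on the grid frame")
        conv = converged.get(name)
        if conv is None:
            conv = np.isfinite(pmap)
        vals = pmap.ravel()[inside]
        good = conv.ravel()[inside] & np.isfinite(vals)
        sums = np.zeros(n)
        cnts = np.zeros(n)
        np.add.at(sums, idx[good], vals[good])
        np.add.at(cnts, idx[good], 1.0)
        with np.errstate(invalid="ignore"):
            df[f"mean_{name}"] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        df[f"n_conv_{name}"] = cnts.astype(int)

    if truth_maps:
        for name, tmap in truth_maps.items():
            vals = tmap.ravel()[inside]
            sums = np.zeros(n)
            cnts = np.zeros(n)
            np.add.at(sums, idx, vals)
            np.add.at(cnts, idx, 1.0)
            df[f"truth_{name}"] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)

    xs, ys = apply_rigid(cells["x_mm"].to_numpy(), cells["y_mm"].to_numpy(),
                         transform)
    cell_roi = grid.cell_of_points(xs, ys)
    cats = cells["intensity"].to_numpy()
    df["n_cells"] = 0
    df["percent_positive"] = np.nan
    df["intensity"] = np.nan
    df["hif_score"] = np.nan
    df["hif_label"] = ""
    by_roi = pd.Series(np.arange(cats.size)).groupby(cell_roi)
    for rid, members in by_roi.groups.items():
        if rid < 0:
            continue
        sc = score_roi(cats[np.asarray(members)], cfg.hif_cut)
        df.loc[rid, ["n_cells", "percent_positive", "intensity",
                     "hif_score", "hif_label"]] = (
            sc.n_cells, sc.percent_positive, sc.intensity, sc.score, sc.label)

    was_included = df["included"].to_numpy(bool)
    conv_cols = [c for c in df.columns if c.startswith("n_conv_")]
    no_voxels = np.zeros(n, dtype=bool)
    for c in conv_cols:
        no_voxels |= df[c].to_numpy() == 0
    no_cells = df["n_cells"].to_numpy() == 0
    drop = was_included & (no_voxels | no_cells)
    df.loc[drop, "included"] = False
    df.loc[drop, "exclusion_reason"] = "empty"
    return df


def mark_contralateral_normals(df: pd.DataFrame, grid: RoiGrid,
                               mirror_x_mm: float) -> pd.DataFrame:
    """Flag analysis ROIs under the matched-contralateral design.

    Tumor ROIs that survived inclusion are analysed as-is; a normal ROI
    enters the analysis only if it is the mirror image (across the
    mid-sagittal plane at ``mirror_x_mm``) of an included tumor ROI.
    Adds a boolean ``in_analysis`` column.
    """
    df = df.copy()
    included = df["included"].to_numpy(bool)
    tumor = included & (df["tissue_class"] == "tumor").to_numpy()
    normal = included & (df["tissue_class"] == "normal").to_numpy()
    tx = df.loc[tumor, "center_x_mm"].to_numpy()
    ty = df.loc[tumor, "center_y_mm"].to_numpy()
    mirrored = grid.cell_of_points(2.0 * mirror_x_mm - tx, ty)
    target = np.zeros(len(df), dtype=bool)
    target[mirrored[mirrored >= 0]] = True
    df["in_analysis"] = tumor | (normal & target)
    return df
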