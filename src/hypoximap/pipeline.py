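"""End-to-end orchestration: simulate -> fit -> grid -> score -> stats.

A study is a pooled cohort of phantom animals.  Per animal the
pipeline generates (or loads) the label volume, truth maps, MR series
and cell table, selects the largest tumor slice, fits IVIM and R2* on
that slice, tessellates it into 1 mm² ROIs, applies the inclusion
rules, scores HIF per ROI and pools the per-animal tables (with an
``animal`` column) into one tidy ROI table feeding the statistics
report.  Every artefact is written in its declared format and a run
manifest records seeds, config hash, versions and stage wall-times.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .config import StudyConfig, config_hash
from .ivim import fit_ivim_full, fit_ivim_segmented
from .phantom import (NORMAL, TissueLabelVolume, TruthMaps, generate_label_volume,
                      generate_truth_maps, stage_rng, synthesize_cell_table,
                      synthesize_dwi, synthesize_mege)
from .r2star import R2StarFitConfig, estimate_background_sigma, fit_r2star
from .roi import (aggregate_roi, build_roi_table, mark_contralateral_normals,
                  select_largest_tumor_slice, tessellate)
from .stats import build_report, report_to_markdown

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)   # name -> wall seconds
    warnings: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _animal_config(cfg: StudyConfig, animal: int):
    """Per-animal phantom config: derived seed and drawn tumor volume."""
    rng = stage_rng(cfg.seed, f"animal-{animal}")
    vol = cfg.phantom.tumor_volume_mm3
    if cfg.tumor_volume_sd_mm3 > 0:
        draw = rng.normal(vol, cfg.tumor_volume_sd_mm3)
        lo, hi = vol - 2.0 * cfg.tumor_volume_sd_mm3, vol + 2.0 * cfg.tumor_volume_sd_mm3
        vol = float(np.clip(draw, lo, hi))
    return cfg.phantom.model_copy(update={
        "tumor_volume_mm3": vol,
        "seed": int(rng.integers(0, 2**31 - 1)),
    })


def analyze_animal(cfg: StudyConfig, labels: TissueLabelVolume,
                   dwi, mege, cells: pd.DataFrame,
                   truth: TruthMaps | None = None) -> pd.DataFrame:
    """Fit, grid and score one animal; returns its per-ROI table."""
    k = select_largest_tumor_slice(labels)
    lab2d = labels.labels[:, :, k]
    brain = lab2d >= NORMAL

    dwi_slice = dwi.data[:, :, k, :]
    if cfg.ivim_method == "full":
        ivim_maps = fit_ivim_full(dwi_slice[brain], dwi.b_values, cfg.ivim)
    else:
        ivim_maps = fit_ivim_segmented(dwi_slice[brain], dwi.b_values, cfg.ivim)

    mege_slice = mege.data[:, :, k, :]
    r2_cfg = cfg.r2star
    if r2_cfg.noise_sigma is None:
        sigma_hat = estimate_background_sigma(mege_slice)
        if sigma_hat > 0:
            r2_cfg = R2StarFitConfig(**(r2_cfg.model_dump() | {"noise_sigma": sigma_hat}))
    r2_maps = fit_r2star(mege_slice[brain], mege.echo_times_s, r2_cfg)

    def to_plane(vals, fill=np.nan):
        out = np.full(lab2d.shape, fill, dtype=float)
        out[brain] = vals
        return out

    param_maps = {
        "d": to_plane(ivim_maps.d), "dstar": to_plane(ivim_maps.dstar),
        "f": to_plane(ivim_maps.f), "perfusion": to_plane(ivim_maps.perfusion),
        "r2star": to_plane(r2_maps.r2star),
    }
    conv_ivim = to_plane(ivim_maps.converged.astype(float), 0.0) > 0
    conv_r2 = to_plane(r2_maps.converged.astype(float), 0.0) > 0
    converged = {"d": conv_ivim, "dstar": conv_ivim, "f": conv_ivim,
                 "perfusion": conv_ivim, "r2star": conv_r2}

    grid = tessellate(lab2d.shape, labels.voxel_size_mm[:2],
                      cfg.analysis.roi_side_mm)
    table = build_roi_table(lab2d, grid, cfg.analysis)
    truth_maps = None
    if truth is not None:
        truth_maps = {name: getattr(truth, name)[:, :, k]
                      for name in ("d", "dstar", "f", "r2star", "hif")}
    table = aggregate_roi(table, grid, param_maps, converged,
                          cells[cells["slice"] == k], cfg.analysis,
                          truth_maps=truth_maps)
    if cfg.analysis.normal_roi_policy == "contralateral":
        mirror_x = labels.labels.shape[0] * labels.voxel_size_mm[0] / 2.0
        table = mark_contralateral_normals(table, grid, mirror_x)
    else:
        table["in_analysis"] = table["included"]
    table["slice"] = k
    return table


def simulate_animal(cfg: StudyConfig, animal: int):
    """Generate one animal's labels, truth maps, MR series and cells."""
    pcfg = _animal_config(cfg, animal)
    labels = generate_label_volume(pcfg)
    truth = generate_truth_maps(labels, pcfg)
    dwi = synthesize_dwi(truth, cfg.protocol.b_values, pcfg.noise_sigma, pcfg.seed)
    mege = synthesize_mege(truth, cfg.protocol.echo_times_s, pcfg.noise_sigma,
                           pcfg.seed)
    k = select_largest_tumor_slice(labels)
    cells = synthesize_cell_table(truth, labels, k, pcfg.cell_density_per_mm2,
                                  pcfg.seed)
    return labels, truth, dwi, mege, cells


def null_study_config(seed: int) -> StudyConfig:
    """Null-calibration study: no couplings, no group differences.

    Both tissues share one marginal distribution (the tumor marginals,
    so the high/low HIF dichotomy stays populated), all core-rim
    gradients and latent couplings are zero, and the latent fields are
    spatially independent so ROI values are exchangeable and the
    nominal test level applies.  The phantom is scaled down (48x48x8
    voxels, ~57 mm³ tumor) so that replicate batteries stay cheap.
    """
    from .config import PhantomConfig, TUMOR_TISSUE
    phantom = PhantomConfig(
        shape=(48, 48, 8),
        brain_semiaxes_mm=(4.8, 3.9, 3.2),
        tumor_center_offset_mm=(-1.3, 0.0, 0.0),
        tumor_volume_mm3=57.0,
        coupling_r2star=0.0, coupling_dstar=0.0,
        hif_core_rim_gradient=0.0, dstar_core_rim_gradient=0.0,
        f_core_rim_gradient=0.0,
        latent_smooth_mm=0.0,
        normal=TUMOR_TISSUE, tumor=TUMOR_TISSUE,
        seed=seed,
    )
    return StudyConfig(n_animals=2, tumor_volume_sd_mm3=0.0, phantom=phantom,
                       write_volumes=False, seed=seed)


def run_study_tables(cfg: StudyConfig) -> pd.DataFrame:
    """Simulate and analyse every animal in memory; pooled ROI table."""
    tables = []
    for a in range(cfg.n_animals):
        labels, truth, dwi, mege, cells = simulate_animal(cfg, a)
        table = analyze_animal(cfg, labels, dwi, mege, cells, truth)
        table.insert(0, "animal", a)
        tables.append(table)
    return pd.concat(tables, ignore_index=True)


def run_pipeline(cfg: StudyConfig, outdir: str | Path,
                 seed: int | None = None, resume: bool = False,
                 inputs: dict | None = None) -> RunManifest:
    """Run the full study and write all artefacts under ``outdir``.

    ``inputs`` optionally maps animal index -> dict of file paths
    (labels, dwi, mege, cells) to analyse user-supplied data instead of
    simulating; those animals skip the simulator and follow the
    identical downstream code path.  With ``resume=True``, per-animal
    ROI tables already on disk are reused.
    """
    if seed is not None:
        cfg = cfg.model_copy(update={"seed": int(seed)})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config_hash(cfg), seed=cfg.seed,
                           version=__version__)
    (outdir / "config.json").write_text(
        json.dumps(cfg.model_dump(mode="json"), indent=2, sort_keys=True))

    tables = []
    for a in range(cfg.n_animals):
        t0 = time.perf_counter()
        table_path = outdir / f"roi_table_animal{a}.csv"
        if resume and table_path.exists():
            table = pd.read_csv(table_path, float_precision="round_trip")
            tables.append(table)
            manifest.stages[f"animal{a}"] = 0.0
            continue
        if inputs and a in inputs:
            paths = inputs[a]
            labels = io.load_labels(paths["labels"])
            dwi = io.load_dwi(paths["dwi"])
            mege = io.load_mege(paths["mege"])
            cells = io.load_cells(paths["cells"])
            truth = None
        else:
            labels, truth, dwi, mege, cells = simulate_animal(cfg, a)
            if cfg.write_volumes:
                io.save_labels(labels, outdir / f"labels_animal{a}.nii.gz")
                io.save_dwi(dwi, outdir / f"dwi_animal{a}.nii.gz")
                io.save_mege(mege, outdir / f"mege_animal{a}.nii.gz")
                io.save_cells(cells, outdir / f"cells_animal{a}.csv")
        table = analyze_animal(cfg, labels, dwi, mege, cells, truth)
        table.insert(0, "animal", a)
        table.to_csv(table_path, index=False, float_format="%.17g")
        tables.append(table)
        manifest.stages[f"animal{a}"] = round(time.perf_counter() - t0, 3)

    pooled = pd.concat(tables, ignore_index=True)
    pooled.to_csv(outdir / "roi_table.csv", index=False, float_format="%.17g")

    t0 = time.perf_counter()
    report = build_report(pooled)
    manifest.stages["stats"] = round(time.perf_counter() - t0, 3)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (outdir / "report.md").write_text(report_to_markdown(report))

    analysed = pooled[pooled["in_analysis"]] if "in_analysis" in pooled \
        else pooled[pooled["included"]]
    scatter = analysed[analysed["tissue_class"] == "tumor"][
        ["animal", "roi_id", "mean_r2star", "mean_dstar", "mean_d", "mean_f",
         "mean_perfusion", "hif_score"]]
    scatter.to_csv(outdir / "correlation_scatter.csv", index=False,
                   float_format="%.17g")

    manifest.counts = {
        "rois_total": int(len(pooled)),
        "rois_included": int(pooled["included"].sum()),
        "rois_in_analysis": int(analysed.shape[0]),
        "tumor_in_analysis": int((analysed["tissue_class"] == "tumor").sum()),
        "normal_in_analysis": int((analysed["tissue_class"] == "normal").sum()),
        "excluded_by_reason": {
            k: int(v) for k, v in pooled.loc[~pooled["included"],
                                             "exclusion_reason"]
            .value_counts().items()},
    }
    logger.info("included ROIs: %s", manifest.counts)
    manifest.outputs = {"roi_table": str(outdir / "roi_table.csv"),
                        "report": str(outdir / "report.json")}
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
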