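"""NIfTI / JSON-sidecar / CSV input-output helpers.

4D series are stored as NIfTI with the 4th dimension indexing b-value
or echo; the b-values (s/mm²) or echo times (seconds) live in a JSON
sidecar next to the image.  Cell tables and ROI tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import DwiSeries, MegeSeries, TissueLabelVolume


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm[:3]) + [1.0])
    return aff


def save_nifti(data: np.ndarray, voxel_size_mm, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data), _affine(voxel_size_mm))
    img.header.set_zooms(tuple(voxel_size_mm[:3]) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), zooms


def save_sidecar(values, key: str, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({key: list(map(float, values))}, indent=2))
    return path


def load_sidecar(path: str | Path, key: str) -> tuple[float, ...]:
    data = json.loads(Path(path).read_text())
    return tuple(float(v) for v in data[key])


def save_labels(labels: TissueLabelVolume, path: str | Path) -> Path:
    return save_nifti(labels.labels.astype(np.int16), labels.voxel_size_mm, path)


def load_labels(path: str | Path) -> TissueLabelVolume:
    data, zooms = load_nifti(path)
    return TissueLabelVolume(labels=data.astype(np.int8), voxel_size_mm=zooms)


def save_dwi(series: DwiSeries, path: str | Path) -> Path:
    p = save_nifti(series.data, series.voxel_size_mm, path)
    save_sidecar(series.b_values, "b_values", p.with_suffix("").with_suffix(".json"))
    return p


def load_dwi(path: str | Path) -> DwiSeries:
    data, zooms = load_nifti(path)
    b = load_sidecar(Path(path).with_suffix("").with_suffix(".json"), "b_values")
    return DwiSeries(data=data, b_values=b, voxel_size_mm=zooms)


def save_mege(series: MegeSeries, path: str | Path) -> Path:
    p = save_nifti(series.data, series.voxel_size_mm, path)
    save_sidecar(series.echo_times_s, "echo_times_s",
                 p.with_suffix("").with_suffix(".json"))
    return p


def load_mege(path: str | Path) -> MegeSeries:
    data, zooms = load_nifti(path)
    te = load_sidecar(Path(path).with_suffix("").with_suffix(".json"),
                      "echo_times_s")
    return MegeSeries(data=data, echo_times_s=te, voxel_size_mm=zooms)


def save_cells(cells: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cells.to_csv(path, index=False, float_format="%.17g")
    return path


def load_cells(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
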