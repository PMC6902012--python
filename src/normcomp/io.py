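"""NIfTI-1 reading and writing for images, maps and displacement fields.

Time series are 4D NIfTI; displacement fields are 4D NIfTI with 3 components
on the last axis in mm, axis order (x, y, z, component), compatible with
common deformation-field exports (a 5D (x, y, z, 1, 3) file is squeezed on
read).  Sidecar JSON records generator parameters when images are written by
the simulator.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import GridSpec
from .images import ScalarMap, TimeSeriesImage
from .spatial import DeformationField


def _grid_from_nifti(img: nib.Nifti1Image) -> GridSpec:
    return GridSpec.from_affine(img.affine, tuple(img.shape[:3]))


def save_timeseries(image: TimeSeriesImage, path: str | Path, sidecar: dict | None = None) -> None:
    nii = nib.Nifti1Image(image.data.astype(np.float64), image.grid.affine)
    nii.header.set_zooms(tuple(image.grid.voxel_size) + (image.tr,))
    nii.header.set_xyzt_units("mm", "sec")
    nib.save(nii, str(path))
    meta = {"tr": image.tr}
    if sidecar:
        meta.update(sidecar)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def load_timeseries(path: str | Path, mask: np.ndarray | None = None) -> TimeSeriesImage:
    nii = nib.load(str(path))
    data = np.asarray(nii.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D time-series NIfTI, got shape {data.shape}")
    grid = _grid_from_nifti(nii)
    zooms = nii.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        tr = float(json.loads(sidecar.read_text()).get("tr", tr))
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    return TimeSeriesImage(data, grid, tr, mask)


def save_map(map_: ScalarMap, path: str | Path) -> None:
    nii = nib.Nifti1Image(map_.data.astype(np.float64), map_.grid.affine)
    nib.save(nii, str(path))


def save_mask(mask: np.ndarray, grid: GridSpec, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), grid.affine), str(path))


def load_mask(path: str | Path) -> np.ndarray:
    nii = nib.load(str(path))
    return np.asarray(nii.dataobj) > 0


def load_map(path: str | Path, mask: np.ndarray | None = None) -> ScalarMap:
    nii = nib.load(str(path))
    data = np.asarray(nii.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D scalar NIfTI, got shape {data.shape}")
    grid = _grid_from_nifti(nii)
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    return ScalarMap(data, grid, mask)


def save_deformation(field: DeformationField, path: str | Path) -> None:
    nii = nib.Nifti1Image(field.displacement.astype(np.float64), field.grid.affine)
    nii.header.set_intent("vector")
    nib.save(nii, str(path))
    if field.inverse_displacement is not None:
        p = Path(str(path))
        inv_path = p.with_name(p.name.replace(".nii", "_inverse.nii", 1))
        inv = nib.Nifti1Image(
            field.inverse_displacement.astype(np.float64), field.source_grid.affine
        )
        inv.header.set_intent("vector")
        nib.save(inv, str(inv_path))


def load_deformation(path: str | Path, inverse_path: str | Path | None = None) -> DeformationField:
    nii = nib.load(str(path))
    disp = np.asarray(nii.dataobj, dtype=float)
    if disp.ndim == 5 and disp.shape[3] == 1:  # SPM-style (x, y, z, 1, 3)
        disp = disp[:, :, :, 0, :]
    if disp.ndim != 4 or disp.shape[-1] != 3:
        raise ValueError(
            f"{path}: displacement field must be (x, y, z, 3) in mm, got {disp.shape}"
        )
    if not np.all(np.isfinite(disp)):
        raise ValueError(f"{path}: displacement field contains non-finite values")
    grid = _grid_from_nifti(nii)
    inv = None
    src_grid = None
    if inverse_path is not None:
        inv_nii = nib.load(str(inverse_path))
        inv = np.asarray(inv_nii.dataobj, dtype=float)
        if inv.ndim == 5 and inv.shape[3] == 1:
            inv = inv[:, :, :, 0, :]
        src_grid = _grid_from_nifti(inv_nii)
    return DeformationField(disp, grid, inv, src_grid)
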