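"""Voxel grids for standard-space and native-space images.

A :class:`GridSpec` describes an axis-aligned sampling lattice: voxel size in
mm, and a world-space bounding box whose corners are the *centers* of the
first and last voxels (the SPM "bounding box" convention, so the MNI box
[-90,-126,-72; 90,90,108] at 3 mm yields a 61 x 73 x 61 grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default MNI-space bounding box (mm), SPM/DPABI convention.
MNI_BBOX = ((-90.0, -126.0, -72.0), (90.0, 90.0, 108.0))


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned voxel lattice with a diagonal voxel-to-world affine.

    Parameters
    ----------
    voxel_size
        Edge length of a voxel along each axis, mm; strictly positive.
    bbox_min, bbox_max
        World-mm coordinates of the centers of the corner voxels.
    """

    voxel_size: tuple[float, float, float]
    bbox_min: tuple[float, float, float]
    bbox_max: tuple[float, float, float]

    def __post_init__(self) -> None:
        # normalize to plain-float tuples so configs serialize cleanly
        object.__setattr__(self, "voxel_size", tuple(float(x) for x in self.voxel_size))
        object.__setattr__(self, "bbox_min", tuple(float(x) for x in self.bbox_min))
        object.__setattr__(self, "bbox_max", tuple(float(x) for x in self.bbox_max))
        vs = np.asarray(self.voxel_size, dtype=float)
        lo = np.asarray(self.bbox_min, dtype=float)
        hi = np.asarray(self.bbox_max, dtype=float)
        if vs.shape != (3,) or lo.shape != (3,) or hi.shape != (3,):
            raise ValueError("voxel_size and bounding-box corners must be 3-vectors")
        if np.any(vs <= 0):
            raise ValueError(f"voxel_size must be strictly positive, got {tuple(vs)}")
        if np.any(hi < lo):
            raise ValueError("bbox_max must be >= bbox_min on all axes")
        n = (hi - lo) / vs
        if np.any(np.abs(n - np.round(n)) > 1e-6):
            raise ValueError(
                "bounding box span must be an integer number of voxels per axis; "
                f"got fractional counts {tuple(n)}"
            )

    # ------------------------------------------------------------------ #

    @property
    def shape(self) -> tuple[int, int, int]:
        """Grid dimensions: (max - min) / voxel_size + 1 per axis."""
        vs = np.asarray(self.voxel_size, dtype=float)
        lo = np.asarray(self.bbox_min, dtype=float)
        hi = np.asarray(self.bbox_max, dtype=float)
        return tuple(int(round(x)) + 1 for x in (hi - lo) / vs)

    @property
    def n_voxels(self) -> int:
        sx, sy, sz = self.shape
        return sx * sy * sz

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index (0-based, voxel centers) -> world-mm affine."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.bbox_min
        return aff

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world-mm coordinates (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.voxel_size) + np.asarray(self.bbox_min)

    def world_to_voxel(self, world: np.ndarray) -> np.ndarray:
        """Map world-mm coordinates (..., 3) to continuous voxel indices."""
        world = np.asarray(world, dtype=float)
        return (world - np.asarray(self.bbox_min)) / np.asarray(self.voxel_size)

    def voxel_centers_world(self) -> np.ndarray:
        """World-mm coordinates of every voxel center, shape (*shape, 3)."""
        axes = [
            np.asarray(self.bbox_min)[d]
            + np.asarray(self.voxel_size)[d] * np.arange(self.shape[d])
            for d in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    # ------------------------------------------------------------------ #

    @classmethod
    def from_shape(
        cls,
        shape: tuple[int, int, int],
        voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0),
        center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "GridSpec":
        """Grid of a given shape, centered on a world point."""
        shape_a = np.asarray(shape, dtype=float)
        vs = np.asarray(voxel_size, dtype=float)
        half = (shape_a - 1) * vs / 2.0
        c = np.asarray(center, dtype=float)
        return cls(tuple(vs), tuple(c - half), tuple(c + half))

    @classmethod
    def from_affine(cls, affine: np.ndarray, shape: tuple[int, int, int]) -> "GridSpec":
        """Build a GridSpec from a diagonal, positive NIfTI affine.

        Oblique or negative-determinant affines are rejected: this package's
        resampling assumes an axis-aligned RAS lattice.
        """
        affine = np.asarray(affine, dtype=float)
        lin = affine[:3, :3]
        off = lin - np.diag(np.diag(lin))
        if np.max(np.abs(off)) > 1e-4 or np.any(np.diag(lin) <= 0):
            raise ValueError(
                "only axis-aligned grids with positive voxel sizes are supported; "
                f"got affine linear part\n{lin}"
            )
        vs = np.diag(lin)
        lo = affine[:3, 3]
        hi = lo + vs * (np.asarray(shape, dtype=float) - 1)
        return cls(tuple(vs), tuple(lo), tuple(hi))

    @classmethod
    def mni_3mm(cls) -> "GridSpec":
        """Full MNI bounding box at 3 mm isotropic (61 x 73 x 61)."""
        return cls((3.0, 3.0, 3.0), MNI_BBOX[0], MNI_BBOX[1])

    @classmethod
    def desk(cls) -> "GridSpec":
        """Small default grid (20 x 24 x 18 at 3 mm) for seconds-scale studies."""
        return cls.from_shape((20, 24, 18))
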