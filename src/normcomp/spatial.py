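"""Spatial normalization machinery: deformation fields and resampling.

Warps are applied by *pull* (backward) resampling: each output voxel looks up
its value at a displaced position in the source image.  This matches how SPM
and kindred tools write normalized images and is well defined for any field.

Conventions (used everywhere in this package):

* world coordinates are mm in a right-handed axis-aligned frame;
* voxel indices are 0-based and refer to voxel centers;
* a displacement field lives on the *output* grid and stores, per output
  voxel, the mm offset from that voxel's world position to the point of the
  source image it samples (``source_world = out_world + displacement``);
* the inverse field lives on the source grid and maps source-space points
  back to output space (``out_world = src_world + inverse_displacement``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.ndimage import map_coordinates, spline_filter

from .grids import GridSpec
from .images import ScalarMap, TimeSeriesImage

InterpKind = Literal["trilinear", "nearest"]

#: Composition contract: |forward(inverse(x)) - x| <= this many voxels, for
#: points at least 2 voxels from the box faces whose forward image stays
#: inside the grid.
COMPOSITION_TOL_VOX = 0.05
#: Fixed-point solver runs tighter than the contract so that off-node
#: interpolation of both fields stays within it.
INVERSION_TOL_VOX = 0.005
INVERSION_MAX_ITER = 200


@dataclass
class Interpolator:
    """Resampling scheme: trilinear (SPM default) or nearest neighbour.

    Out-of-field / out-of-mask handling is a mask update, not a fill value:
    an output voxel is valid only if its full interpolation support (all 8
    trilinear corners, or the single nearest voxel) lies inside the source
    mask.  Values at invalid voxels are set to 0 but must never enter
    statistics.
    """

    kind: InterpKind = "trilinear"

    def __post_init__(self) -> None:
        if self.kind not in ("trilinear", "nearest"):
            raise ValueError(f"unknown interpolation kind: {self.kind!r}")

    @property
    def order(self) -> int:
        return 1 if self.kind == "trilinear" else 0


@dataclass(frozen=True)
class SeedROI:
    """Spherical seed region, world-mm center and radius."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("seed radius must be positive (mm)")


@dataclass
class DeformationField:
    """Voxelwise warp from an output grid into a source image's space.

    Attributes
    ----------
    displacement
        Array ``(*grid.shape, 3)``, mm, pull convention (see module docs).
    grid
        Output-space grid the displacement is sampled on.
    inverse_displacement
        Array ``(*source_grid.shape, 3)`` mapping source space back to output
        space; computed by fixed-point iteration (``invert_displacement``).
    source_grid
        Grid of the source/native image; defaults to ``grid`` (the synthetic
        studies warp within one lattice).
    """

    displacement: np.ndarray
    grid: GridSpec
    inverse_displacement: np.ndarray | None = None
    source_grid: GridSpec | None = None

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.shape != tuple(self.grid.shape) + (3,):
            raise ValueError(
                f"displacement shape {self.displacement.shape} does not match "
                f"grid {self.grid.shape} + (3,)"
            )
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement field contains non-finite values")
        if self.source_grid is None:
            self.source_grid = self.grid
        if self.inverse_displacement is not None:
            inv = np.asarray(self.inverse_displacement, dtype=float)
            if inv.shape != tuple(self.source_grid.shape) + (3,):
                raise ValueError("inverse_displacement shape does not match source grid")
            if not np.all(np.isfinite(inv)):
                raise ValueError("inverse displacement contains non-finite values")
            self.inverse_displacement = inv

    # ------------------------------------------------------------------ #

    def sample_displacement(self, world_points: np.ndarray) -> np.ndarray:
        """Interpolate the forward displacement at world points (..., 3)."""
        return _sample_vector_field(self.displacement, self.grid, world_points)

    def map_points(self, world_points: np.ndarray) -> np.ndarray:
        """Forward map: output-space world points -> source-space world points."""
        world_points = np.asarray(world_points, dtype=float)
        return world_points + self.sample_displacement(world_points)

    def map_points_inverse(self, world_points: np.ndarray) -> np.ndarray:
        """Inverse map: source-space world points -> output-space world points."""
        if self.inverse_displacement is None:
            raise ValueError("field has no inverse_displacement; run invert_displacement")
        world_points = np.asarray(world_points, dtype=float)
        return world_points + _sample_vector_field(
            self.inverse_displacement, self.source_grid, world_points
        )


def _sample_vector_field(
    field: np.ndarray, grid: GridSpec, world_points: np.ndarray
) -> np.ndarray:
    """Sample a (*grid.shape, 3) vector field at world points (..., 3).

    Cubic-spline interpolation: displacement fields are smooth by
    construction, and linear interpolation between lattice nodes would
    dominate the forward-inverse composition error.  (Image intensities are
    never resampled here - the image resampler is trilinear/nearest.)
    Outside the grid the field is clamped to its edge values (mode="nearest"),
    which keeps the fixed-point inversion stable near the boundary.
    """
    pts = np.asarray(world_points, dtype=float)
    vox = grid.world_to_voxel(pts).reshape(-1, 3).T  # (3, N)
    out = np.empty((vox.shape[1], 3))
    for c in range(3):
        out[:, c] = map_coordinates(field[..., c], vox, order=3, mode="nearest")
    return out.reshape(pts.shape)


# ---------------------------------------------------------------------- #
# Inversion
# ---------------------------------------------------------------------- #


def invert_displacement(
    displacement: np.ndarray,
    grid: GridSpec,
    source_grid: GridSpec | None = None,
    tol_vox: float = INVERSION_TOL_VOX,
    max_iter: int = INVERSION_MAX_ITER,
) -> np.ndarray:
    """Invert a displacement field by fixed-point iteration.

    Solves ``v(y) = -u(y + v(y))`` at every source-grid voxel center ``y``;
    the solution satisfies ``(y + v(y)) + u_interp(y + v(y)) = y``.  The
    update is damped (halved) whenever the residual grows, which rescues
    oscillating iterations near steep field gradients.

    Raises
    ------
    RuntimeError
        If the residual is still above ``tol_vox`` (in voxel units of
        ``grid``) after ``max_iter`` iterations.  This occurs only for
        fields steep enough to violate diffeomorphism.
    """
    if source_grid is None:
        source_grid = grid
    y = source_grid.voxel_centers_world()
    v = np.zeros_like(y)
    min_voxel = float(np.min(grid.voxel_size))
    # Prefilter the spline coefficients once; every iteration then samples
    # with prefilter=False, which is what dominates the solver's cost.
    coeffs = np.stack(
        [spline_filter(displacement[..., c], order=3, mode="nearest") for c in range(3)],
        axis=-1,
    )

    def sample_u(pts: np.ndarray) -> np.ndarray:
        vox = grid.world_to_voxel(pts).reshape(-1, 3).T
        out = np.empty((vox.shape[1], 3))
        for c in range(3):
            out[:, c] = map_coordinates(
                coeffs[..., c], vox, order=3, mode="nearest", prefilter=False
            )
        return out.reshape(pts.shape)

    step = 1.0
    prev_res = np.inf
    for _ in range(max_iter):
        target = -sample_u(y + v)
        delta = target - v
        res = float(np.max(np.linalg.norm(delta, axis=-1))) / min_voxel
        if res <= tol_vox:
            return v + delta
        if res > prev_res:
            step = max(step * 0.5, 0.125)
        v = v + step * delta
        prev_res = res
    raise RuntimeError(
        f"displacement inversion did not converge: residual {res:.4f} voxels "
        f"after {max_iter} iterations (tolerance {tol_vox}); the field is "
        "likely too steep to be diffeomorphic at this amplitude/smoothness"
    )


# ---------------------------------------------------------------------- #
# Resampling
# ---------------------------------------------------------------------- #


def _pull_coordinates(field: DeformationField, source_grid: GridSpec) -> np.ndarray:
    """Continuous source-voxel coordinates sampled by each output voxel, (3, N)."""
    out_world = field.grid.voxel_centers_world()
    src_world = out_world + field.displacement
    return source_grid.world_to_voxel(src_world).reshape(-1, 3).T


def _gather(
    data: np.ndarray, mask: np.ndarray, coords: np.ndarray, order: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pull-resample ``data`` (3D or 4D) at continuous voxel coords (3, N).

    Vectorized over points *and* timepoints.  Returns ``(values, support)``
    where support is the interpolation weight falling on in-bounds, in-mask
    source voxels: 1 means the full support is inside the mask.  Out-of-bounds
    corners contribute zero (constant extension).
    """
    shape = data.shape[:3]
    has_t = data.ndim == 4
    flat = data.reshape(-1, data.shape[3]) if has_t else data.reshape(-1)
    maskf = mask.ravel().astype(float)
    n = coords.shape[1]

    def corner(ix, iy, iz, w):
        inb = (
            (ix >= 0) & (ix < shape[0])
            & (iy >= 0) & (iy < shape[1])
            & (iz >= 0) & (iz < shape[2])
        )
        lin = np.ravel_multi_index(
            (np.clip(ix, 0, shape[0] - 1), np.clip(iy, 0, shape[1] - 1),
             np.clip(iz, 0, shape[2] - 1)), shape
        )
        wi = w * inb
        vals = wi[:, None] * flat[lin] if has_t else wi * flat[lin]
        return vals, wi * maskf[lin]

    if order == 0:
        # nearest neighbour: round half up, one source voxel per point
        idx = np.floor(coords + 0.5).astype(np.int64)
        return corner(idx[0], idx[1], idx[2], np.ones(n))

    base = np.floor(coords).astype(np.int64)
    t = coords - base
    vals = np.zeros((n, data.shape[3])) if has_t else np.zeros(n)
    support = np.zeros(n)
    for dx in (0, 1):
        wx = t[0] if dx else 1.0 - t[0]
        for dy in (0, 1):
            wy = t[1] if dy else 1.0 - t[1]
            for dz in (0, 1):
                wz = t[2] if dz else 1.0 - t[2]
                v, s = corner(base[0] + dx, base[1] + dy, base[2] + dz, wx * wy * wz)
                vals += v
                support += s
    return vals, support


def warp_volume(
    volume: ScalarMap,
    field: DeformationField,
    interp: Interpolator | InterpKind = "trilinear",
) -> ScalarMap:
    """Pull-resample a scalar map through a deformation field (Postnorm step).

    Each output voxel takes the interpolated source value at its displaced
    position.  The output mask marks voxels whose full interpolation support
    is inside the source mask; values elsewhere are zeroed.
    """
    if isinstance(interp, str):
        interp = Interpolator(interp)
    coords = _pull_coordinates(field, volume.grid)
    out_shape = tuple(field.grid.shape)
    vals, support = _gather(volume.data, volume.mask, coords, interp.order)
    warped = vals.reshape(out_shape)
    valid = (support > 1.0 - 1e-9).reshape(out_shape)
    warped[~valid] = 0.0
    return ScalarMap(warped, field.grid, valid, name=volume.name)


def warp_timeseries(
    image: TimeSeriesImage,
    field: DeformationField,
    interp: Interpolator | InterpKind = "trilinear",
) -> TimeSeriesImage:
    """Pull-resample every timepoint with one shared field (Prenorm step).

    Equivalent to :func:`warp_volume` applied independently per timepoint
    with identical coordinates and weights; the repetition time carries over.
    """
    if isinstance(interp, str):
        interp = Interpolator(interp)
    coords = _pull_coordinates(field, image.grid)
    out_shape = tuple(field.grid.shape)
    vals, support = _gather(image.data, image.mask, coords, interp.order)
    warped = vals.reshape(out_shape + (image.n_timepoints,))
    valid = (support > 1.0 - 1e-9).reshape(out_shape)
    warped[~valid] = 0.0
    return TimeSeriesImage(warped, field.grid, image.tr, valid, info=dict(image.info))


# ---------------------------------------------------------------------- #
# Seed ROIs
# ---------------------------------------------------------------------- #


def sphere_voxels(grid: GridSpec, roi: SeedROI) -> np.ndarray:
    """Voxel indices (N, 3) whose centers fall within the ROI sphere."""
    centers = grid.voxel_centers_world()
    d = np.linalg.norm(centers - np.asarray(roi.center), axis=-1)
    return np.argwhere(d <= roi.radius)


def inverse_map_roi(
    roi: SeedROI, field: DeformationField, native_grid: GridSpec | None = None
) -> np.ndarray:
    """Inverse-normalize a standard-space seed sphere into native space.

    Returns the (N, 3) native-grid voxel indices whose inverse-mapped centers
    fall within ``roi.radius`` of ``roi.center``.  Raises if the result is
    empty, which signals an implausible warp for any radius of a voxel or
    more.
    """
    if native_grid is None:
        native_grid = field.source_grid
    if field.inverse_displacement is None:
        raise ValueError("field has no inverse_displacement; run invert_displacement")
    centers = native_grid.voxel_centers_world()
    mapped = centers + _sample_vector_field(
        field.inverse_displacement, field.source_grid, centers
    )
    d = np.linalg.norm(mapped - np.asarray(roi.center), axis=-1)
    idx = np.argwhere(d <= roi.radius)
    if idx.size == 0:
        raise RuntimeError(
            f"inverse-mapped seed ROI at {roi.center} (r={roi.radius} mm) contains "
            "no native voxels; the deformation field is implausible for this grid"
        )
    return idx
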