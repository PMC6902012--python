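"""In-memory image containers: 4D time series and 3D scalar maps.

Both carry a :class:`~normcomp.grids.GridSpec` and a boolean validity mask.
The mask is authoritative: array values at invalid voxels are storage, not
data, and every statistic in this package honours the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grids import GridSpec


@dataclass
class TimeSeriesImage:
    """4D BOLD-like image: intensities indexed (x, y, z, t).

    Attributes
    ----------
    data
        Float array, shape ``(*grid.shape, n_timepoints)``.
    grid
        Sampling lattice of the spatial axes.
    tr
        Repetition time (sampling interval) in seconds.
    mask
        Boolean in-brain indicator, shape ``grid.shape``.
    info
        Free-form provenance (simulation parameters, embedded-signal truth).
    """

    data: np.ndarray
    grid: GridSpec
    tr: float
    mask: np.ndarray
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError(f"time-series data must be 4D, got shape {self.data.shape}")
        if self.data.shape[:3] != tuple(self.grid.shape):
            raise ValueError(
                f"spatial shape {self.data.shape[:3]} does not match grid {self.grid.shape}"
            )
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must equal the spatial shape of the data")
        if self.n_timepoints < 2:
            raise ValueError("a time series needs at least 2 timepoints")
        if self.tr <= 0:
            raise ValueError("tr must be positive (seconds)")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in Hz."""
        return 1.0 / (2.0 * self.tr)

    def with_data(self, data: np.ndarray) -> "TimeSeriesImage":
        """Copy of this image with new intensities on the same geometry."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class ScalarMap:
    """3D feature or statistic map on a grid, with a validity mask."""

    data: np.ndarray
    grid: GridSpec
    mask: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError(
                f"map shape {self.data.shape} does not match grid {self.grid.shape}"
            )
        if self.mask.shape != self.data.shape:
            raise ValueError("mask shape must equal map shape")

    def valid_values(self) -> np.ndarray:
        """1D array of values at valid voxels."""
        return self.data[self.mask]

    def mean(self) -> float:
        """Mean over valid voxels."""
        vals = self.valid_values()
        if vals.size == 0:
            raise ValueError("map has no valid voxels")
        return float(vals.mean())


def constant_map(grid: GridSpec, value: float, mask: np.ndarray | None = None) -> ScalarMap:
    """Spatially constant map; valid everywhere unless a mask is given."""
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    return ScalarMap(np.full(grid.shape, float(value)), grid, mask)
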