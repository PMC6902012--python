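"""Group-level statistics over stacks of feature maps.

All voxelwise tests run only where every subject's map is valid; p-values are
corrected across in-mask voxels with Benjamini-Hochberg FDR (the package's
substitute for cluster-level random-field correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .grids import GridSpec
from .images import ScalarMap

#: Display bands conventionally used for ICC maps (no inferential meaning).
ICC_BANDS = {
    "poor": (-np.inf, 0.2),
    "fair": (0.2, 0.4),
    "moderate": (0.4, 0.6),
    "substantial": (0.6, 0.8),
    "almost_perfect": (0.8, np.inf),
}


@dataclass
class CohortMaps:
    """Ordered subject stack of congruent scalar maps.

    ``data`` has shape (n_subjects, *grid.shape); ``mask`` is the common
    validity mask (AND across subjects) - statistics are computed only where
    all subjects are valid.
    """

    data: np.ndarray
    grid: GridSpec
    mask: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4 or self.data.shape[1:] != tuple(self.grid.shape):
            raise ValueError(
                f"cohort stack shape {self.data.shape} does not match grid {self.grid.shape}"
            )
        if self.mask.shape != self.data.shape[1:]:
            raise ValueError("common mask shape must match the grid")
        if not self.labels:
            self.labels = list(range(self.data.shape[0]))

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @classmethod
    def from_maps(cls, maps: list[ScalarMap], labels: list | None = None) -> "CohortMaps":
        if not maps:
            raise ValueError("empty map list")
        grid = maps[0].grid
        for m in maps:
            if tuple(m.grid.shape) != tuple(grid.shape):
                raise ValueError("all maps in a cohort must share one grid")
        data = np.stack([m.data for m in maps])
        mask = np.logical_and.reduce([m.mask for m in maps])
        return cls(data, grid, mask, labels=labels or [])

    def group_mean_map(self) -> ScalarMap:
        out = self.data.mean(axis=0)
        out[~self.mask] = 0.0
        return ScalarMap(out, self.grid, self.mask.copy(), name="group_mean")


@dataclass
class TTestResult:
    t: ScalarMap
    p: ScalarMap
    q: ScalarMap


@dataclass
class ICCMap:
    """Voxelwise ICC with its variance components."""

    icc: ScalarMap
    vb: np.ndarray
    vw: np.ndarray


# ---------------------------------------------------------------------- #
# Helpers
# ---------------------------------------------------------------------- #


def _fdr_q(p: np.ndarray, valid: np.ndarray) -> np.ndarray:
    q = np.ones_like(p)
    if valid.any():
        _, q_valid, _, _ = multipletests(p[valid], method="fdr_bh")
        q[valid] = q_valid
    return q


def _package_t(t, p, valid, grid) -> TTestResult:
    q = _fdr_q(p, valid)
    t = np.where(valid, t, 0.0)
    p = np.where(valid, p, 1.0)
    mk = lambda a, nm: ScalarMap(a, grid, valid.copy(), name=nm)
    return TTestResult(mk(t, "t"), mk(p, "p"), mk(q, "q"))


# ---------------------------------------------------------------------- #
# Maps
# ---------------------------------------------------------------------- #


def cv_map(cohort: CohortMaps, mean_floor: float | None = None) -> ScalarMap:
    """Across-subject coefficient of variation: sample SD divided by mean.

    Voxels whose |mean| falls below a floor (default 1e-6 of the map scale,
    taken as the largest |mean| over valid voxels) are masked: CV is badly
    defined near zero.
    """
    if cohort.n_subjects < 2:
        raise ValueError("CV needs at least 2 subjects")
    mean = cohort.data.mean(axis=0)
    sd = cohort.data.std(axis=0, ddof=1)
    valid = cohort.mask.copy()
    if not valid.any():
        raise ValueError("cohort has no commonly valid voxels")
    if mean_floor is None:
        mean_floor = 1e-6 * float(np.max(np.abs(mean[valid])))
    valid &= np.abs(mean) > mean_floor
    out = np.zeros_like(mean)
    out[valid] = sd[valid] / mean[valid]
    return ScalarMap(out, cohort.grid, valid, name="cv")


def paired_t_map(a: CohortMaps, b: CohortMaps) -> TTestResult:
    """Voxelwise paired t-test between two matched cohorts (a - b).

    Classical paired t with n-1 df, two-sided p, BH-FDR q across valid
    voxels.  Voxels with zero difference variance are masked (t undefined).
    """
    if a.n_subjects != b.n_subjects:
        raise ValueError("paired test needs matched subject counts")
    if a.n_subjects < 2:
        raise ValueError("paired t needs at least 2 subjects")
    d = a.data - b.data
    n = a.n_subjects
    dm = d.mean(axis=0)
    dsd = d.std(axis=0, ddof=1)
    # Identically zero differences carry t = 0; zero variance around a
    # nonzero mean would be an infinite t and is masked instead.
    valid = a.mask & b.mask & ((dsd > 0) | (dm == 0))
    t = np.zeros_like(dm)
    pos = valid & (dsd > 0)
    t[pos] = dm[pos] / (dsd[pos] / np.sqrt(n))
    p = np.ones_like(dm)
    p[pos] = 2.0 * sps.t.sf(np.abs(t[pos]), df=n - 1)
    return _package_t(t, p, valid, a.grid)


def one_sample_t_map(cohort: CohortMaps, mu0: float = 0.0) -> TTestResult:
    """Voxelwise one-sample t-test of the stack against mu0."""
    if cohort.n_subjects < 2:
        raise ValueError("one-sample t needs at least 2 subjects")
    n = cohort.n_subjects
    m = cohort.data.mean(axis=0)
    sd = cohort.data.std(axis=0, ddof=1)
    # Same degenerate-case rule as the paired test: exact agreement with mu0
    # is t = 0, zero variance off mu0 is masked.
    valid = cohort.mask & ((sd > 0) | (m == mu0))
    t = np.zeros_like(m)
    pos = valid & (sd > 0)
    t[pos] = (m[pos] - mu0) / (sd[pos] / np.sqrt(n))
    p = np.ones_like(m)
    p[pos] = 2.0 * sps.t.sf(np.abs(t[pos]), df=n - 1)
    return _package_t(t, p, valid, cohort.grid)


def crosscohort_correlation_map(x: CohortMaps, y: CohortMaps) -> TTestResult:
    """Across-subject voxelwise Pearson correlation between two stacks.

    Returns r (in the ``t`` slot's place as a map named "r"), p and q maps.
    Used for simulation-vs-empirical comparisons: the subject order must
    match between the stacks.
    """
    if x.n_subjects != y.n_subjects:
        raise ValueError("correlation needs matched subject counts")
    n = x.n_subjects
    if n < 3:
        raise ValueError("across-subject correlation needs at least 3 subjects")
    xc = x.data - x.data.mean(axis=0)
    yc = y.data - y.data.mean(axis=0)
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum(axis=0))
    valid = x.mask & y.mask & (sx > 0) & (sy > 0)
    r = np.zeros_like(sx)
    r[valid] = (xc * yc).sum(axis=0)[valid] / (sx[valid] * sy[valid])
    r = np.clip(r, -1.0, 1.0)
    p = np.ones_like(r)
    with np.errstate(divide="ignore"):
        tstat = r[valid] * np.sqrt((n - 2) / np.maximum(1.0 - r[valid] ** 2, 1e-300))
    p[valid] = 2.0 * sps.t.sf(np.abs(tstat), df=n - 2)
    res = _package_t(r, p, valid, x.grid)
    res.t.name = "r"
    return res


def icc_map(
    session1: CohortMaps, session2: CohortMaps, method: str = "components"
) -> ICCMap:
    """Voxelwise two-session intraclass correlation, ICC = (Vb-Vw)/(Vb+Vw).

    One-way random-effects ANOVA with k=2 sessions gives MSB (between-subject
    mean square) and MSW (within-subject mean square).  Two readings of
    Vb/Vw are exposed:

    * ``"components"`` (default): Vb = (MSB - MSW)/2 estimates the
      between-subject variance component, Vw = MSW the within-subject one;
      population value (sb^2 - sw^2)/(sb^2 + sw^2).
    * ``"ms"``: Vb = MSB, Vw = MSW, i.e. classical ICC(1,1) at k=2;
      population value sb^2/(sb^2 + sw^2).

    Both are monotone transforms of MSB/MSW, so orderings and medians-based
    comparisons agree between them.  Negative estimates are reported, not
    clamped; voxels with Vb + Vw <= 0 are masked.
    """
    if session1.n_subjects != session2.n_subjects:
        raise ValueError("ICC needs matched subjects across sessions")
    if session1.n_subjects < 2:
        raise ValueError("ICC needs at least 2 subjects")
    if method not in ("components", "ms"):
        raise ValueError(f"unknown ICC method {method!r}")
    y1, y2 = session1.data, session2.data
    m = (y1 + y2) / 2.0
    msb = 2.0 * m.var(axis=0, ddof=1)
    msw = ((y1 - y2) ** 2).mean(axis=0) / 2.0
    if method == "components":
        vb = (msb - msw) / 2.0
    else:
        vb = msb
    vw = msw
    denom = vb + vw
    valid = session1.mask & session2.mask & (denom > 0)
    icc = np.zeros_like(denom)
    icc[valid] = (vb[valid] - vw[valid]) / denom[valid]
    return ICCMap(ScalarMap(icc, session1.grid, valid, name="icc"), vb, vw)


def icc_band_fractions(icc: ICCMap) -> dict[str, float]:
    """Fraction of valid voxels per conventional ICC display band."""
    vals = icc.icc.valid_values()
    if vals.size == 0:
        return {k: float("nan") for k in ICC_BANDS}
    return {
        name: float(((vals >= lo) & (vals < hi)).mean())
        for name, (lo, hi) in ICC_BANDS.items()
    }


def histogram_summary(
    map_: ScalarMap,
    region_masks: dict[str, np.ndarray] | None = None,
    n_bins: int = 50,
    value_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Binned counts of a map per region; counts sum to region voxel counts.

    ``region_masks`` defaults to the map's own validity mask under the name
    "whole".  The binning (edges) is recorded in the output table.
    """
    if region_masks is None:
        region_masks = {"whole": map_.mask}
    rows = []
    for name, rmask in region_masks.items():
        rmask = np.asarray(rmask, dtype=bool) & map_.mask
        vals = map_.data[rmask]
        if vals.size == 0:
            raise ValueError(f"region {name!r} has no valid voxels")
        rng = value_range or (float(vals.min()), float(vals.max()))
        counts, edges = np.histogram(vals, bins=n_bins, range=rng)
        # np.histogram drops values outside an explicit range; fold them into
        # the edge bins so counts conserve the region total.
        if value_range is not None:
            counts[0] += int((vals < rng[0]).sum())
            counts[-1] += int((vals > rng[1]).sum())
        for i in range(n_bins):
            rows.append(
                {"region": name, "bin_left": edges[i], "bin_right": edges[i + 1],
                 "count": int(counts[i])}
            )
    return pd.DataFrame(rows)
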