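"""Temporal rs-fMRI features: tSNR, ALFF, ReHo, seed-based FC.

Processing order is fixed: confound regression first, then an ideal
frequency-domain band-pass (0.01-0.08 Hz) for FC and ReHo only; tSNR and
ALFF consume the regressed-but-unfiltered series.

Definitions:

* tSNR - temporal mean over temporal sample SD (ddof=1), per voxel;
* ALFF - mean of the one-sided amplitude spectrum (2/N)|DFT| over the
  in-band bins of the demeaned series;
* ReHo - Kendall's coefficient of concordance W of a voxel with its 26
  neighbours (27-voxel cube), no tie correction;
* FC - Pearson correlation of each voxel with the mean seed time course.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .images import ScalarMap, TimeSeriesImage

#: ReHo is computed only where at least this many of the 27 cube voxels are in-mask.
REHO_MIN_NEIGHBORS = 14


@dataclass(frozen=True)
class BandSpec:
    """Frequency band in Hz; defaults are the canonical low-frequency band."""

    low: float = 0.01
    high: float = 0.08

    def validate(self, tr: float) -> None:
        nyquist = 1.0 / (2.0 * tr)
        if not (0 <= self.low < self.high < nyquist):
            raise ValueError(
                f"band [{self.low}, {self.high}] Hz invalid for TR {tr} s "
                f"(Nyquist {nyquist} Hz)"
            )

    def bins(self, n_timepoints: int, tr: float) -> np.ndarray:
        """Boolean selector over rfft bins, inclusive at both quantized edges."""
        self.validate(tr)
        freqs = np.fft.rfftfreq(n_timepoints, d=tr)
        eps = 1e-12
        return (freqs >= self.low - eps) & (freqs <= self.high + eps) & (freqs > 0)


@dataclass
class FeatureMapSet:
    """The four feature maps of one subject/session plus their provenance."""

    maps: dict[str, ScalarMap]
    provenance: dict

    def __getitem__(self, key: str) -> ScalarMap:
        return self.maps[key]


# ---------------------------------------------------------------------- #
# Preprocessing
# ---------------------------------------------------------------------- #


def regress_confounds(
    image: TimeSeriesImage,
    confounds: np.ndarray | None = None,
    include_linear_trend: bool = False,
) -> TimeSeriesImage:
    """OLS-remove nuisance regressors and (optionally) a linear trend.

    Per voxel the series is replaced by its least-squares residual on
    [intercept, confounds, trend], with the fitted intercept added back so
    mean-dependent features (tSNR) stay defined.  Residuals are orthogonal to
    every regressor.  Collinear columns are dropped with a warning.
    """
    n_t = image.n_timepoints
    cols = [np.ones(n_t)]
    if confounds is not None and np.asarray(confounds).size:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.shape[0] != n_t:
            raise ValueError(
                f"confounds have {confounds.shape[0]} rows for {n_t} timepoints"
            )
        cols.extend(confounds.T)
    if include_linear_trend:
        cols.append(np.linspace(-1.0, 1.0, n_t))
    if len(cols) == 1:
        return image.with_data(image.data.copy())

    x = np.column_stack(cols)
    # Drop collinear columns (keep earliest) via rank-revealing QR on the fly.
    keep: list[int] = []
    for j in range(x.shape[1]):
        trial = x[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
    if len(keep) < x.shape[1]:
        warnings.warn(
            f"dropping {x.shape[1] - len(keep)} collinear confound column(s)",
            stacklevel=2,
        )
        x = x[:, keep]

    y = image.data.reshape(-1, n_t).T  # (T, V)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    out = (resid + beta[0]).T.reshape(image.data.shape)  # intercept added back
    out[~image.mask] = 0.0
    return image.with_data(out)


def bandpass(image: TimeSeriesImage, band: BandSpec = BandSpec()) -> TimeSeriesImage:
    """Ideal rectangular frequency-domain band-pass filter.

    DFT coefficients with ``low <= f <= high`` (after quantization to bin
    frequencies) are retained; all others zeroed, except DC, which is kept so
    mean-dependent quantities stay defined (FC and ReHo are mean-invariant,
    so the retained mean is inert for them).
    """
    keep = band.bins(image.n_timepoints, image.tr)
    if not keep.any():
        raise ValueError("band is empty after quantization to DFT bins")
    spec = np.fft.rfft(image.data, axis=3)
    selector = keep.copy()
    selector[0] = True  # retain DC
    spec[..., ~selector] = 0.0
    out = np.fft.irfft(spec, n=image.n_timepoints, axis=3)
    out[~image.mask] = 0.0
    return image.with_data(out)


# ---------------------------------------------------------------------- #
# Features
# ---------------------------------------------------------------------- #


def compute_tsnr(image: TimeSeriesImage) -> ScalarMap:
    """Temporal SNR map: mean / sample SD (ddof=1) per in-mask voxel.

    Zero-SD voxels are masked invalid rather than emitting infinities.
    """
    mean = image.data.mean(axis=3)
    sd = image.data.std(axis=3, ddof=1)
    valid = image.mask & (sd > 0)
    out = np.zeros(image.data.shape[:3])
    out[valid] = mean[valid] / sd[valid]
    return ScalarMap(out, image.grid, valid, name="tsnr")


def compute_alff(image: TimeSeriesImage, band: BandSpec = BandSpec()) -> ScalarMap:
    """ALFF map: mean one-sided spectral amplitude over the low-frequency band.

    The series is demeaned, transformed by FFT, and amplitudes are scaled as
    (2/N)|DFT|; ALFF averages the amplitudes of bins with low <= f <= high.
    Applied to the unfiltered (confound-regressed) series.
    """
    keep = band.bins(image.n_timepoints, image.tr)
    if not keep.any():
        raise ValueError("no DFT bins inside the band at this length/TR")
    x = image.data - image.data.mean(axis=3, keepdims=True)
    amp = (2.0 / image.n_timepoints) * np.abs(np.fft.rfft(x, axis=3))
    out = amp[..., keep].mean(axis=3)
    out[~image.mask] = 0.0
    return ScalarMap(out, image.grid, image.mask.copy(), name="alff")


def kendalls_w(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance of K series over n timepoints.

    W = 12 S / (K^2 (n^3 - n)) with S the sum of squared deviations of the
    per-timepoint rank sums from their mean; no tie correction.
    """
    series = np.asarray(series, dtype=float)
    k, n = series.shape
    if k < 2:
        raise ValueError("concordance needs at least 2 series")
    ranks = rankdata(series, axis=1)
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    return 12.0 * s / (k**2 * (n**3 - n))


def compute_reho(
    image: TimeSeriesImage, min_neighbors: int = REHO_MIN_NEIGHBORS
) -> ScalarMap:
    """ReHo map: Kendall's W over each voxel's 27-voxel cube (self + 26).

    Expects a band-passed series.  Only in-mask neighbours enter; voxels with
    fewer than ``min_neighbors`` in-mask cube voxels are masked.
    """
    n = image.n_timepoints
    maskf = image.mask.astype(float)
    ranks = rankdata(image.data, axis=3)
    ranks = ranks * maskf[..., None]

    kernel3 = np.ones((3, 3, 3))
    counts = ndimage.correlate(maskf, kernel3, mode="constant", cval=0.0)
    counts = np.round(counts).astype(int)
    rank_sums = ndimage.correlate(
        ranks, kernel3[..., None], mode="constant", cval=0.0
    )
    expected = counts[..., None] * (n + 1) / 2.0
    s = ((rank_sums - expected) ** 2).sum(axis=3)

    valid = image.mask & (counts >= min_neighbors)
    out = np.zeros(image.data.shape[:3])
    k = counts[valid].astype(float)
    out[valid] = 12.0 * s[valid] / (k**2 * (n**3 - n))
    return ScalarMap(out, image.grid, valid, name="reho")


def compute_fc(image: TimeSeriesImage, seed_voxels: np.ndarray) -> ScalarMap:
    """Seed-based FC map: Pearson r of each voxel with the seed-mean course.

    Expects a band-passed series and a non-empty (N, 3) seed voxel-index set.
    Zero-variance voxels (or a zero-variance seed mean) are masked.
    """
    seed_voxels = np.asarray(seed_voxels)
    if seed_voxels.size == 0:
        raise ValueError("seed voxel set is empty")
    seed = image.data[seed_voxels[:, 0], seed_voxels[:, 1], seed_voxels[:, 2], :]
    seed_mean = seed.mean(axis=0)
    s = seed_mean - seed_mean.mean()
    s_norm = float(np.sqrt((s**2).sum()))
    if s_norm == 0:
        raise ValueError("seed mean time course has zero variance")

    x = image.data - image.data.mean(axis=3, keepdims=True)
    x_norm = np.sqrt((x**2).sum(axis=3))
    valid = image.mask & (x_norm > 0)
    out = np.zeros(image.data.shape[:3])
    out[valid] = (x[valid] @ s) / (x_norm[valid] * s_norm)
    return ScalarMap(out, image.grid, valid, name="fc")


def compute_dmn_mask(fc_cohorts: list, alpha: float = 0.05) -> np.ndarray:
    """Union of voxels with significantly positive group FC in any strategy.

    Each element of ``fc_cohorts`` is a CohortMaps stack of one strategy's FC
    maps; a one-sample t-test against zero with BH-FDR at ``alpha`` flags the
    positive voxels, and the union across strategies forms the mask.
    """
    from .stats import one_sample_t_map

    if not fc_cohorts:
        raise ValueError("need at least one FC cohort")
    union = None
    for cohort in fc_cohorts:
        res = one_sample_t_map(cohort, mu0=0.0)
        sig = res.t.mask & (res.t.data > 0) & (res.q.data < alpha)
        union = sig if union is None else (union | sig)
    return union
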