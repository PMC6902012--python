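"""Synthetic rs-fMRI inputs: constant-tSNR noise images, warps, cohorts.

The generator reproduces the constant-tSNR phantom design: every in-brain
voxel carries an independent white-noise time course affinely rescaled so its
*sample* mean and sample tSNR (mean over SD, SD with denominator n-1) hit the
targets exactly - the constancy is arithmetic, not statistical.  Defaults are
the study conditions: 190 timepoints, TR 2 s, mean 1000, tSNR 100.

Per-subject warps stand in for anatomical normalization parameters: Gaussian
vector fields smoothed to a stated FWHM and rescaled to an exact RMS
magnitude, with per-subject magnitudes drawn from a range - the knob that
produces algorithmic intersubject variability downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .grids import GridSpec
from .images import TimeSeriesImage
from .spatial import DeformationField, invert_displacement

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SimulationParams:
    """Targets for the constant-tSNR noise generator.

    target_mean and target_tsnr are hit exactly (sample statistics) at every
    in-mask voxel; n_timepoints is the series length after discards.
    """

    target_mean: float = 1000.0
    target_tsnr: float = 100.0
    n_timepoints: int = 190
    tr: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.target_mean <= 0:
            raise ValueError("target_mean must be positive")
        if self.target_tsnr <= 0:
            raise ValueError("target_tsnr must be positive")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 timepoints (SD undefined otherwise)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout and the sources of between/within-subject variation.

    deformation_amplitude_range
        Per-subject RMS warp magnitude (mm) drawn uniformly from this range.
    deformation_smoothness
        FWHM (mm) of the Gaussian-smoothed random displacement fields.
    between_subject_sd / within_subject_sd
        SDs (tSNR units) of additive subject and session offsets to the
        target tSNR, used to plant genuine signal in reliability studies.
        Both default to 0: the baseline phantom cohort has no individual
        differences.
    share_session_warp
        If True, both sessions of a subject reuse one field; default False
        re-draws the field per session at the subject's amplitude, emulating
        per-scan estimation of normalization parameters.
    """

    n_subjects: int = 20
    n_sessions: int = 1
    deformation_amplitude_range: tuple[float, float] = (2.0, 4.0)
    deformation_smoothness: float = 25.0
    between_subject_sd: float = 0.0
    within_subject_sd: float = 0.0
    share_session_warp: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_sessions not in (1, 2):
            raise ValueError("n_sessions must be 1 or 2")
        lo, hi = self.deformation_amplitude_range
        if lo < 0 or hi < lo:
            raise ValueError("deformation amplitude range must be 0 <= lo <= hi")
        if self.deformation_smoothness <= 0:
            raise ValueError("deformation_smoothness must be positive (mm FWHM)")
        if self.between_subject_sd < 0 or self.within_subject_sd < 0:
            raise ValueError("variance controls must be non-negative")


@dataclass
class SessionData:
    session: int
    image: TimeSeriesImage
    deformation: DeformationField


@dataclass
class SubjectData:
    subject: int
    amplitude: float
    target_tsnr: float
    sessions: list[SessionData]


# ---------------------------------------------------------------------- #
# Masks
# ---------------------------------------------------------------------- #


def ellipsoid_mask(grid: GridSpec) -> np.ndarray:
    """Axis-aligned ellipsoid inscribed in the grid box (~52% fill).

    A brain-in-field-of-view stand-in: it leaves out-of-mask edge voxels so
    boundary handling in the resampler is actually exercised.
    """
    shape = np.asarray(grid.shape, dtype=float)
    idx = np.indices(grid.shape).transpose(1, 2, 3, 0).astype(float)
    center = (shape - 1) / 2.0
    semi = shape / 2.0
    r2 = np.sum(((idx - center) / semi) ** 2, axis=-1)
    return r2 <= 1.0


# ---------------------------------------------------------------------- #
# Generators
# ---------------------------------------------------------------------- #


def generate_constant_tsnr_image(
    params: SimulationParams,
    grid: GridSpec,
    mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> TimeSeriesImage:
    """White-noise 4D image with exact sample mean and tSNR at every voxel.

    Each in-mask voxel's Gaussian series is standardized to zero sample mean
    and unit sample SD (ddof=1), then rescaled to
    ``target_mean + (target_mean / target_tsnr) * z``.  Out-of-mask voxels
    are zero.  Deterministic under ``params.rng_seed`` (or a supplied rng).
    """
    if mask is None:
        mask = ellipsoid_mask(grid)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(grid.shape):
        raise ValueError("mask shape does not match grid")
    if not mask.any():
        raise ValueError("mask is empty")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)

    n_vox = int(mask.sum())
    series = rng.standard_normal((n_vox, params.n_timepoints))
    sd = series.std(axis=1, ddof=1)
    # A zero-variance draw cannot be standardized; resample those rows.
    # (Measure zero for continuous draws; the guard keeps the contract total.)
    for _ in range(10):
        bad = sd == 0
        if not bad.any():
            break
        series[bad] = rng.standard_normal((int(bad.sum()), params.n_timepoints))
        sd = series.std(axis=1, ddof=1)
    z = (series - series.mean(axis=1, keepdims=True)) / sd[:, None]
    scaled = params.target_mean + (params.target_mean / params.target_tsnr) * z

    data = np.zeros(tuple(grid.shape) + (params.n_timepoints,))
    data[mask] = scaled
    return TimeSeriesImage(
        data, grid, params.tr, mask,
        info={"target_mean": params.target_mean, "target_tsnr": params.target_tsnr},
    )


def generate_deformation(
    grid: GridSpec,
    amplitude: float,
    smoothness: float,
    rng_seed: int | None = None,
    rng: np.random.Generator | None = None,
    source_grid: GridSpec | None = None,
    invert: bool = True,
) -> DeformationField:
    """Smooth random displacement field with exact RMS magnitude.

    An i.i.d. Gaussian 3-vector field is smoothed to ``smoothness`` mm FWHM
    and rescaled so the root-mean-square of |displacement| equals
    ``amplitude`` mm exactly.  The inverse field is computed by fixed-point
    iteration (tolerance 0.05 voxel).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0 (mm)")
    if smoothness <= 0:
        raise ValueError("smoothness must be > 0 (mm FWHM)")
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    shape = tuple(grid.shape)
    if amplitude == 0.0:
        zero = np.zeros(shape + (3,))
        src = source_grid or grid
        return DeformationField(zero, grid, np.zeros(tuple(src.shape) + (3,)), src)

    disp = rng.standard_normal(shape + (3,))
    sigma_vox = smoothness * _FWHM_TO_SIGMA / np.asarray(grid.voxel_size)
    for c in range(3):
        disp[..., c] = gaussian_filter(disp[..., c], sigma=sigma_vox, mode="reflect")
    rms = float(np.sqrt(np.mean(np.sum(disp**2, axis=-1))))
    if rms == 0.0:
        raise RuntimeError("degenerate zero field after smoothing")
    disp *= amplitude / rms

    inv = None
    if invert:
        inv = invert_displacement(disp, grid, source_grid=source_grid)
    return DeformationField(disp, grid, inv, source_grid)


def generate_confounds(
    n_timepoints: int, n_regressors: int, rng_seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Smooth random nuisance series, column-standardized (time x regressor).

    Stand-ins for motion/CSF/WM regressors: white noise smoothed along time
    (sigma 4 samples), then scaled to zero mean and unit SD (ddof=1).
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    if n_regressors == 0:
        return np.empty((n_timepoints, 0))
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    x = rng.standard_normal((n_timepoints, n_regressors))
    x = gaussian_filter1d(x, sigma=4.0, axis=0, mode="reflect")
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return x / sd


def band_limited_course(
    n_timepoints: int, tr: float, band: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-SD random time course with energy confined to a frequency band."""
    low, high = band
    x = rng.standard_normal(n_timepoints)
    freqs = np.fft.rfftfreq(n_timepoints, d=tr)
    spec = np.fft.rfft(x)
    keep = (freqs >= low) & (freqs <= high) & (freqs > 0)
    if not keep.any():
        raise ValueError("band contains no DFT bins at this length/TR")
    spec[~keep] = 0.0
    y = np.fft.irfft(spec, n=n_timepoints)
    return (y - y.mean()) / y.std(ddof=1)


def embed_network_signal(
    image: TimeSeriesImage,
    roi_sets: list[np.ndarray],
    signal_sd: float,
    rng_seed: int | None = None,
    rng: np.random.Generator | None = None,
    band: tuple[float, float] = (0.01, 0.08),
) -> TimeSeriesImage:
    """Add one shared band-limited source to every voxel of each ROI.

    ``roi_sets`` is a list of (N, 3) voxel-index arrays; all must lie inside
    the image mask.  The source is zero-mean so voxel means are untouched;
    temporal SD (hence tSNR/ALFF) changes as expected for added signal.  The
    true design is recorded under ``info['network_signal']`` for recovery
    tests.  ``signal_sd=0`` returns an identical copy.
    """
    if signal_sd < 0:
        raise ValueError("signal_sd must be >= 0")
    out = image.with_data(image.data.copy())
    for k, roi in enumerate(roi_sets):
        roi = np.asarray(roi)
        if roi.ndim != 2 or roi.shape[1] != 3:
            raise ValueError(f"ROI {k} must be an (N, 3) voxel-index array")
        if not image.mask[roi[:, 0], roi[:, 1], roi[:, 2]].all():
            raise ValueError(f"ROI {k} has voxels outside the image mask")
    if signal_sd > 0:
        if rng is None:
            rng = np.random.default_rng(rng_seed)
        source = band_limited_course(image.n_timepoints, image.tr, band, rng)
        for roi in roi_sets:
            roi = np.asarray(roi)
            out.data[roi[:, 0], roi[:, 1], roi[:, 2], :] += signal_sd * source
    out.info["network_signal"] = {
        "signal_sd": float(signal_sd),
        "band": tuple(band),
        "rois": [np.asarray(r).tolist() for r in roi_sets],
        "shared_source": True,
    }
    return out


# ---------------------------------------------------------------------- #
# Cohorts
# ---------------------------------------------------------------------- #


def generate_cohort(
    spec: CohortSpec,
    params: SimulationParams,
    grid: GridSpec,
    mask: np.ndarray | None = None,
    invert_fields: bool = True,
) -> list[SubjectData]:
    """Simulate a cohort of (time series, warp) pairs, subject x session.

    One root seed (``spec.rng_seed``); child seeds are spawned per subject
    and per session via ``numpy.random.SeedSequence`` so subjects are
    independent yet the whole cohort is reproducible bit-for-bit.

    Each subject draws a warp magnitude from ``deformation_amplitude_range``;
    sessions of a subject share the field only if ``share_session_warp``.
    Subject/session tSNR offsets (``between_subject_sd``/``within_subject_sd``)
    perturb the generator's target tSNR; with both at 0 (default) every image
    is an exact constant-tSNR phantom.
    """
    if mask is None:
        mask = ellipsoid_mask(grid)
    root = np.random.SeedSequence(spec.rng_seed)
    subject_seeds = root.spawn(spec.n_subjects)
    cohort: list[SubjectData] = []
    lo, hi = spec.deformation_amplitude_range
    for i, ss in enumerate(subject_seeds):
        draw_ss, warp_ss, *session_seeds = ss.spawn(2 + spec.n_sessions)
        draw_rng = np.random.default_rng(draw_ss)
        amplitude = float(draw_rng.uniform(lo, hi))
        b_i = (
            float(draw_rng.normal(0.0, spec.between_subject_sd))
            if spec.between_subject_sd > 0 else 0.0
        )
        shared_field = None
        if spec.share_session_warp:
            shared_field = generate_deformation(
                grid, amplitude, spec.deformation_smoothness,
                rng=np.random.default_rng(warp_ss), invert=invert_fields,
            )
        sessions = []
        for j, sess_ss in enumerate(session_seeds):
            noise_ss, sess_warp_ss, offset_ss = sess_ss.spawn(3)
            w_ij = (
                float(np.random.default_rng(offset_ss).normal(0.0, spec.within_subject_sd))
                if spec.within_subject_sd > 0 else 0.0
            )
            tsnr_ij = max(params.target_tsnr + b_i + w_ij, 5.0)
            p_ij = replace(params, target_tsnr=tsnr_ij)
            image = generate_constant_tsnr_image(
                p_ij, grid, mask, rng=np.random.default_rng(noise_ss)
            )
            if shared_field is not None:
                field_ij = shared_field
            else:
                field_ij = generate_deformation(
                    grid, amplitude, spec.deformation_smoothness,
                    rng=np.random.default_rng(sess_warp_ss), invert=invert_fields,
                )
            sessions.append(SessionData(session=j, image=image, deformation=field_ij))
        cohort.append(
            SubjectData(subject=i, amplitude=amplitude,
                        target_tsnr=params.target_tsnr + b_i, sessions=sessions)
        )
    return cohort
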