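"""End-to-end study orchestration: Prenorm vs Postnorm over a cohort.

A study takes each subject's (time series, warp) pair through one or both
normalization orders:

* **prenorm** - warp the time series into standard space, then compute the
  features there (seed used directly in standard space);
* **postnorm** - compute the features in native space (seed inverse-mapped),
  then warp each feature map.

Both branches share identical preprocessing (confound regression) before the
branch point; the band-pass for FC/ReHo runs inside each branch, so prenorm
filters the warped series and postnorm the native series.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import (
    BandSpec,
    FeatureMapSet,
    bandpass,
    compute_alff,
    compute_dmn_mask,
    compute_fc,
    compute_reho,
    compute_tsnr,
    regress_confounds,
)
from .grids import GridSpec
from .images import ScalarMap, TimeSeriesImage
from .io import load_deformation, load_mask, load_timeseries
from .simulate import (
    CohortSpec,
    SimulationParams,
    ellipsoid_mask,
    embed_network_signal,
    generate_cohort,
    generate_confounds,
)
from .spatial import (
    DeformationField,
    Interpolator,
    SeedROI,
    inverse_map_roi,
    sphere_voxels,
    warp_timeseries,
    warp_volume,
)
from . import stats as gstats

ALL_FEATURES = ("tsnr", "alff", "reho", "fc")
ALL_STRATEGIES = ("prenorm", "postnorm")
REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class NetworkSignalSpec:
    """Ground-truth correlated signal: spherical ROIs sharing one source."""

    rois: tuple[SeedROI, ...]
    signal_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.signal_sd < 0:
            raise ValueError("signal_sd must be >= 0")


@dataclass
class StudyConfig:
    """Everything a study needs; a run is reproducible from this + its seeds."""

    grid: GridSpec
    simulation: SimulationParams
    cohort: CohortSpec
    band: BandSpec = BandSpec()
    seed_roi: SeedROI = SeedROI((-5.0, -49.0, 40.0), 6.0)
    interpolator: str = "trilinear"
    strategies: tuple[str, ...] = ALL_STRATEGIES
    features: tuple[str, ...] = ALL_FEATURES
    network_signal: NetworkSignalSpec | None = None
    n_confounds: int = 0
    include_linear_trend: bool = False
    icc_method: str = "components"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.strategies = tuple(self.strategies)
        self.features = tuple(self.features)
        for s in self.strategies:
            if s not in ALL_STRATEGIES:
                raise ValueError(f"unknown strategy {s!r}")
        for f in self.features:
            if f not in ALL_FEATURES:
                raise ValueError(f"unknown feature {f!r}")
        Interpolator(self.interpolator)  # validates

    # -- serialization ------------------------------------------------- #

    def to_dict(self) -> dict:
        d = {
            "grid": {
                "voxel_size": list(self.grid.voxel_size),
                "bbox_min": list(self.grid.bbox_min),
                "bbox_max": list(self.grid.bbox_max),
            },
            "simulation": asdict(self.simulation),
            "cohort": asdict(self.cohort),
            "band": asdict(self.band),
            "seed_roi": {"center": list(self.seed_roi.center), "radius": self.seed_roi.radius},
            "interpolator": self.interpolator,
            "strategies": list(self.strategies),
            "features": list(self.features),
            "network_signal": None,
            "n_confounds": self.n_confounds,
            "include_linear_trend": self.include_linear_trend,
            "icc_method": self.icc_method,
            "alpha": self.alpha,
        }
        if self.network_signal is not None:
            d["network_signal"] = {
                "rois": [
                    {"center": list(r.center), "radius": r.radius}
                    for r in self.network_signal.rois
                ],
                "signal_sd": self.network_signal.signal_sd,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        g = d["grid"]
        ns = None
        if d.get("network_signal"):
            ns = NetworkSignalSpec(
                rois=tuple(
                    SeedROI(tuple(r["center"]), r["radius"])
                    for r in d["network_signal"]["rois"]
                ),
                signal_sd=d["network_signal"]["signal_sd"],
            )
        cohort = d["cohort"].copy()
        cohort["deformation_amplitude_range"] = tuple(cohort["deformation_amplitude_range"])
        return cls(
            grid=GridSpec(tuple(g["voxel_size"]), tuple(g["bbox_min"]), tuple(g["bbox_max"])),
            simulation=SimulationParams(**d["simulation"]),
            cohort=CohortSpec(**cohort),
            band=BandSpec(**d["band"]),
            seed_roi=SeedROI(tuple(d["seed_roi"]["center"]), d["seed_roi"]["radius"]),
            interpolator=d.get("interpolator", "trilinear"),
            strategies=tuple(d.get("strategies", ALL_STRATEGIES)),
            features=tuple(d.get("features", ALL_FEATURES)),
            network_signal=ns,
            n_confounds=d.get("n_confounds", 0),
            include_linear_trend=d.get("include_linear_trend", False),
            icc_method=d.get("icc_method", "components"),
            alpha=d.get("alpha", 0.05),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def with_seed(self, seed: int) -> "StudyConfig":
        """Copy of the config with both generator seeds re-rooted at ``seed``."""
        return dataclasses.replace(
            self,
            simulation=dataclasses.replace(self.simulation, rng_seed=seed),
            cohort=dataclasses.replace(self.cohort, rng_seed=seed),
        )


# ---------------------------------------------------------------------- #
# Config presets
# ---------------------------------------------------------------------- #


def default_study_config(seed: int = 0) -> StudyConfig:
    """Desk-scale baseline: 20-subject constant-tSNR cohort, both orders.

    The seed ROI sits inside the desk grid's ellipsoid mask (the classic
    precuneus coordinate lies outside the reduced box).
    """
    grid = GridSpec.desk()
    return StudyConfig(
        grid=grid,
        simulation=SimulationParams(rng_seed=seed),
        cohort=CohortSpec(n_subjects=20, rng_seed=seed),
        seed_roi=SeedROI((-6.0, -18.0, 12.0), 6.0),
    )


def direction_study_config(seed: int = 0) -> StudyConfig:
    """Default study plus an embedded two-ROI network signal (shared source).

    The signal SD of 5 on a noise SD of 10 (mean 1000 / tSNR 100) puts the
    in-ROI temporal SNR at 0.5, a realistic resting-state effect size.
    """
    cfg = default_study_config(seed)
    rois = (cfg.seed_roi, SeedROI((9.0, 15.0, -9.0), 6.0))
    return dataclasses.replace(cfg, network_signal=NetworkSignalSpec(rois=rois, signal_sd=5.0))


def reliability_study_config(seed: int = 0, n_subjects: int = 20) -> StudyConfig:
    """Two-session preset for test-retest studies.

    Genuine subject-level signal is planted as target-tSNR offsets
    (between-subject SD 15, within-subject SD 3, in tSNR units); warps are
    re-drawn per session at each subject's amplitude, emulating per-scan
    estimation of normalization parameters.
    """
    cfg = direction_study_config(seed)
    return dataclasses.replace(
        cfg,
        cohort=dataclasses.replace(
            cfg.cohort,
            n_subjects=n_subjects,
            n_sessions=2,
            between_subject_sd=15.0,
            within_subject_sd=3.0,
        ),
    )


# ---------------------------------------------------------------------- #
# Strategy execution
# ---------------------------------------------------------------------- #


def _branch_features(
    pre: TimeSeriesImage,
    field: DeformationField,
    strategy: str,
    cfg: StudyConfig,
) -> FeatureMapSet:
    """Feature maps for one already-preprocessed subject/session."""
    interp = Interpolator(cfg.interpolator)
    maps: dict[str, ScalarMap] = {}
    if strategy == "prenorm":
        warped = warp_timeseries(pre, field, interp)
        if "tsnr" in cfg.features:
            maps["tsnr"] = compute_tsnr(warped)
        if "alff" in cfg.features:
            maps["alff"] = compute_alff(warped, cfg.band)
        if "reho" in cfg.features or "fc" in cfg.features:
            bp = bandpass(warped, cfg.band)
            if "reho" in cfg.features:
                maps["reho"] = compute_reho(bp)
            if "fc" in cfg.features:
                seed_vox = sphere_voxels(field.grid, cfg.seed_roi)
                maps["fc"] = compute_fc(bp, seed_vox)
    elif strategy == "postnorm":
        native: dict[str, ScalarMap] = {}
        if "tsnr" in cfg.features:
            native["tsnr"] = compute_tsnr(pre)
        if "alff" in cfg.features:
            native["alff"] = compute_alff(pre, cfg.band)
        if "reho" in cfg.features or "fc" in cfg.features:
            bp = bandpass(pre, cfg.band)
            if "reho" in cfg.features:
                native["reho"] = compute_reho(bp)
            if "fc" in cfg.features:
                seed_vox = inverse_map_roi(cfg.seed_roi, field)
                native["fc"] = compute_fc(bp, seed_vox)
        maps = {name: warp_volume(m, field, interp) for name, m in native.items()}
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    provenance = {
        "strategy": strategy,
        "interpolator": cfg.interpolator,
        "band": asdict(cfg.band),
        "seed_roi": {"center": list(cfg.seed_roi.center), "radius": cfg.seed_roi.radius},
    }
    return FeatureMapSet(maps=maps, provenance=provenance)


def run_strategy(
    image: TimeSeriesImage,
    field: DeformationField,
    strategy: str,
    cfg: StudyConfig,
    confounds: np.ndarray | None = None,
) -> FeatureMapSet:
    """One subject/session through one normalization order.

    Preprocessing (confound regression, identical in both branches) happens
    here, before the branch point.
    """
    if confounds is not None or cfg.include_linear_trend:
        image = regress_confounds(image, confounds, cfg.include_linear_trend)
    return _branch_features(image, field, strategy, cfg)


# ---------------------------------------------------------------------- #
# Whole studies
# ---------------------------------------------------------------------- #


def _report_hash(report: dict) -> str:
    payload = json.dumps(report, sort_keys=True, default=float).encode()
    return hashlib.sha256(payload).hexdigest()


def run_study(cfg: StudyConfig, out_dir: str | Path | None = None) -> dict:
    """Execute a full study and return its machine-readable report.

    Generates the cohort, runs every requested strategy and feature, applies
    the group-statistics layer (whole-brain summaries, CV, paired tests,
    two-session ICC, DMN mask) and returns a JSON-serializable report.
    Deterministic under the config's seeds; the report carries its own hash.
    """
    grid = cfg.grid
    mask = ellipsoid_mask(grid)
    need_inverse = "fc" in cfg.features and "postnorm" in cfg.strategies
    cohort = generate_cohort(cfg.cohort, cfg.simulation, grid, mask,
                             invert_fields=need_inverse)
    n_sessions = cfg.cohort.n_sessions

    roi_sets = None
    if cfg.network_signal is not None:
        roi_sets = [sphere_voxels(grid, r) for r in cfg.network_signal.rois]

    stacks: dict[tuple[str, str, int], list[ScalarMap]] = {
        (f, s, j): [] for f in cfg.features for s in cfg.strategies for j in range(n_sessions)
    }
    for subj in cohort:
        for sess in subj.sessions:
            image = sess.image
            if roi_sets is not None and cfg.network_signal.signal_sd > 0:
                sig_rng = np.random.default_rng(
                    np.random.SeedSequence([cfg.cohort.rng_seed, 90001, subj.subject, sess.session])
                )
                image = embed_network_signal(
                    image, roi_sets, cfg.network_signal.signal_sd, rng=sig_rng,
                    band=(cfg.band.low, cfg.band.high),
                )
            confounds = None
            if cfg.n_confounds > 0:
                confounds = generate_confounds(
                    image.n_timepoints, cfg.n_confounds,
                    rng=np.random.default_rng(
                        np.random.SeedSequence(
                            [cfg.cohort.rng_seed, 90002, subj.subject, sess.session]
                        )
                    ),
                )
            if confounds is not None or cfg.include_linear_trend:
                image = regress_confounds(image, confounds, cfg.include_linear_trend)
            for strategy in cfg.strategies:
                featset = _branch_features(image, sess.deformation, strategy, cfg)
                for fname, fmap in featset.maps.items():
                    stacks[(fname, strategy, sess.session)].append(fmap)

    cohorts = {
        key: gstats.CohortMaps.from_maps(maps) for key, maps in stacks.items()
    }

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": cfg.to_dict(),
        "n_subjects": cfg.cohort.n_subjects,
        "n_sessions": n_sessions,
        "summaries": {},
        "paired_tests": {},
        "one_sample_tsnr": None,
        "icc": {},
        "dmn_mask_voxels": None,
        "self_check": {},
    }

    # Per-feature / per-strategy whole-brain summaries (session 0).
    subject_means: dict[tuple[str, str], np.ndarray] = {}
    for fname in cfg.features:
        for strategy in cfg.strategies:
            cm = cohorts[(fname, strategy, 0)]
            means = np.array([cm.data[i][cm.mask].mean() for i in range(cm.n_subjects)])
            subject_means[(fname, strategy)] = means
            entry = {
                "whole_brain_mean": float(means.mean()),
                "whole_brain_sd": float(means.std(ddof=1)) if len(means) > 1 else 0.0,
                "n_valid_voxels": int(cm.mask.sum()),
            }
            if cm.n_subjects >= 2:
                cv = gstats.cv_map(cm)
                vals = cv.valid_values()
                entry["cv"] = {
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    "median": float(np.median(vals)),
                    "q01": float(np.quantile(vals, 0.01)),
                    "q99": float(np.quantile(vals, 0.99)),
                }
            report["summaries"][f"{fname}/{strategy}"] = entry

    # Paired Prenorm-vs-Postnorm comparisons (session 0).
    if set(("prenorm", "postnorm")) <= set(cfg.strategies) and cfg.cohort.n_subjects >= 2:
        from scipy import stats as sps

        for fname in cfg.features:
            a = cohorts[(fname, "prenorm", 0)]
            b = cohorts[(fname, "postnorm", 0)]
            res = gstats.paired_t_map(a, b)
            sig = res.q.mask & (res.q.data < cfg.alpha)
            ma = subject_means[(fname, "prenorm")]
            mb = subject_means[(fname, "postnorm")]
            if np.allclose(ma, mb):
                t_wb, p_wb = 0.0, 1.0
            else:
                t_wb, p_wb = sps.ttest_rel(ma, mb)
            report["paired_tests"][fname] = {
                "mean_diff_prenorm_minus_postnorm": float((ma - mb).mean()),
                "wholebrain_t": float(t_wb),
                "wholebrain_p": float(p_wb),
                "frac_voxels_sig_greater": float((sig & (res.t.data > 0)).sum() / max(res.t.mask.sum(), 1)),
                "frac_voxels_sig_less": float((sig & (res.t.data < 0)).sum() / max(res.t.mask.sum(), 1)),
            }

    # One-sample test of Prenorm tSNR against the generator constant.
    if "tsnr" in cfg.features and "prenorm" in cfg.strategies and cfg.cohort.n_subjects >= 2:
        from scipy import stats as sps

        means = subject_means[("tsnr", "prenorm")]
        t, p = sps.ttest_1samp(means, cfg.simulation.target_tsnr)
        report["one_sample_tsnr"] = {
            "reference": cfg.simulation.target_tsnr,
            "group_mean": float(means.mean()),
            "t": float(t),
            "p": float(p),
        }

    # Two-session ICC per feature and strategy.
    if n_sessions == 2 and cfg.cohort.n_subjects >= 2:
        for fname in cfg.features:
            for strategy in cfg.strategies:
                icc = gstats.icc_map(
                    cohorts[(fname, strategy, 0)], cohorts[(fname, strategy, 1)],
                    method=cfg.icc_method,
                )
                vals = icc.icc.valid_values()
                report["icc"][f"{fname}/{strategy}"] = {
                    "median": float(np.median(vals)) if vals.size else float("nan"),
                    "bands": gstats.icc_band_fractions(icc),
                }

    # DMN mask from FC one-sample tests, union over strategies.
    if "fc" in cfg.features and cfg.cohort.n_subjects >= 2:
        fc_stacks = [cohorts[("fc", s, 0)] for s in cfg.strategies]
        dmn = compute_dmn_mask(fc_stacks, alpha=cfg.alpha)
        report["dmn_mask_voxels"] = int(dmn.sum())

    # Direction self-checks mirroring the headline comparisons.
    checks = {}
    if report["paired_tests"]:
        pt = report["paired_tests"]
        if "tsnr" in pt:
            checks["prenorm_tsnr_greater"] = bool(
                pt["tsnr"]["wholebrain_t"] > 0 and pt["tsnr"]["wholebrain_p"] < 0.01
            )
        if "alff" in pt:
            checks["prenorm_alff_smaller"] = bool(
                pt["alff"]["wholebrain_t"] < 0 and pt["alff"]["wholebrain_p"] < 0.01
            )
        if "reho" in pt:
            checks["prenorm_reho_greater"] = bool(
                pt["reho"]["wholebrain_t"] > 0 and pt["reho"]["wholebrain_p"] < 0.01
            )
    if report["icc"]:
        for fname in ("tsnr", "alff"):
            a, b = f"{fname}/postnorm", f"{fname}/prenorm"
            if a in report["icc"] and b in report["icc"]:
                checks[f"postnorm_{fname}_icc_not_lower"] = bool(
                    report["icc"][a]["median"] >= report["icc"][b]["median"]
                )
    report["self_check"] = checks
    report["report_hash"] = _report_hash(report)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        rows = [
            {"feature_strategy": k, **{
                kk: vv for kk, vv in v.items() if not isinstance(vv, dict)
            }}
            for k, v in report["summaries"].items()
        ]
        pd.DataFrame(rows).to_csv(out / "summaries.csv", index=False)
        if report["icc"]:
            pd.DataFrame(
                [{"feature_strategy": k, "median_icc": v["median"], **v["bands"]}
                 for k, v in report["icc"].items()]
            ).to_csv(out / "icc.csv", index=False)
    return report


# ---------------------------------------------------------------------- #
# External (real-data) entry point
# ---------------------------------------------------------------------- #


def load_external_subject(
    bold_path: str | Path,
    field_path: str | Path,
    mask_path: str | Path | None = None,
    inverse_field_path: str | Path | None = None,
) -> tuple[TimeSeriesImage, DeformationField]:
    """Load a real subject: 4D BOLD + displacement-field NIfTI (+ mask).

    The field must be a 3-component NIfTI in mm, pull convention, sampled on
    the output (standard) grid; an optional inverse field is sampled on the
    native grid and must match the BOLD geometry.  Geometry mismatches and
    non-finite fields are hard errors.
    """
    mask = load_mask(mask_path) if mask_path is not None else None
    image = load_timeseries(bold_path, mask=mask)
    if mask is not None and mask.shape != image.data.shape[:3]:
        raise ValueError(
            f"mask shape {mask.shape} does not match BOLD spatial shape "
            f"{image.data.shape[:3]}"
        )
    field = load_deformation(field_path, inverse_path=inverse_field_path)
    if field.source_grid is not None and inverse_field_path is not None:
        if tuple(field.source_grid.shape) != image.data.shape[:3]:
            raise ValueError(
                "inverse field grid does not match the native BOLD grid: "
                f"{field.source_grid.shape} vs {image.data.shape[:3]}"
            )
    else:
        # No inverse supplied: record the BOLD grid as the source geometry.
        field.source_grid = image.grid
    return image, field
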