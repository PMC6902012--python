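#!/usr/bin/env python
"""Order-of-normalization effect on tSNR in the constant-tSNR simulation.

On the default 20-subject cohort this contrasts the two processing orders:

* Postnorm (compute tSNR natively, then warp the map) keeps tSNR at exactly
  the generated constant, so the across-subject CV is exactly zero;
* Prenorm (warp the time series, then compute tSNR) inflates tSNR - trilinear
  resampling averages independent noise, suppressing its variance - and,
  because each subject's warp differs, induces a strictly positive
  across-subject CV from images that carry no individual differences at all.

Writes results/02_tsnr_comparison.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from normcomp import (
    CohortMaps,
    CohortSpec,
    GridSpec,
    SimulationParams,
    compute_tsnr,
    cv_map,
    generate_cohort,
    warp_timeseries,
    warp_volume,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/02_tsnr_comparison.csv"))
    args = ap.parse_args()

    grid = GridSpec.desk()
    params = SimulationParams(rng_seed=args.seed)
    cohort = generate_cohort(
        CohortSpec(n_subjects=20, rng_seed=args.seed), params, grid, invert_fields=False
    )

    stacks = {"postnorm": [], "prenorm": []}
    for subj in cohort:
        sess = subj.sessions[0]
        stacks["postnorm"].append(
            warp_volume(compute_tsnr(sess.image), sess.deformation, "trilinear")
        )
        stacks["prenorm"].append(
            compute_tsnr(warp_timeseries(sess.image, sess.deformation, "trilinear"))
        )

    rows = []
    for strategy, maps in stacks.items():
        cm = CohortMaps.from_maps(maps)
        subject_means = cm.data[:, cm.mask].mean(axis=1)
        cv = cv_map(cm)
        if subject_means.std(ddof=1) > 1e-9:
            t, p = sps.ttest_1samp(subject_means, params.target_tsnr)
        else:  # Postnorm means are numerically identical; the test is moot
            t, p = 0.0, 1.0
        rows.append({
            "strategy": strategy,
            "group_mean_tsnr": float(subject_means.mean()),
            "between_subject_sd": float(subject_means.std(ddof=1)),
            "one_sample_t_vs_100": float(t),
            "one_sample_p": float(p),
            "cv_mean": float(cv.valid_values().mean()),
            "cv_sd": float(cv.valid_values().std(ddof=1)),
            "cv_q01": float(np.quantile(cv.valid_values(), 0.01)),
            "cv_min": float(cv.valid_values().min()),
            "n_valid_voxels": int(cv.mask.sum()),
        })
    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)

    post = df[df.strategy == "postnorm"].iloc[0]
    pre = df[df.strategy == "prenorm"].iloc[0]
    print(f"Postnorm: group mean tSNR {post.group_mean_tsnr:.6f} "
          f"(generated constant preserved), CV everywhere {post.cv_mean:.2e}")
    print(f"Prenorm:  group mean tSNR {pre.group_mean_tsnr:.2f} "
          f"(one-sample t vs 100: t={pre.one_sample_t_vs_100:.1f}, p={pre.one_sample_p:.2g})")
    print(f"Prenorm CV {pre.cv_mean:.3f} +/- {pre.cv_sd:.3f} "
          f"(lowest 1% quantile {pre.cv_q01:.3f}, minimum {pre.cv_min:.3f} > 0): "
          "the normalization order alone manufactures intersubject variability")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
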