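#!/usr/bin/env python
"""Prenorm-vs-Postnorm differences for all four features with embedded signal.

Runs the default study with a two-ROI network signal (shared band-limited
source, temporal SNR 0.5) and paired-tests each feature between the two
normalization orders.  Expected directions: Prenorm raises tSNR and ReHo
(interpolation suppresses noise and correlates neighbours), lowers ALFF
(less residual fluctuation amplitude), and perturbs FC near the seed.

Writes results/03_feature_directions.csv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from normcomp import direction_study_config, run_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/03_feature_directions.csv"))
    args = ap.parse_args()

    report = run_study(direction_study_config(seed=args.seed))

    rows = []
    for feature, res in report["paired_tests"].items():
        rows.append({
            "feature": feature,
            "prenorm_mean": report["summaries"][f"{feature}/prenorm"]["whole_brain_mean"],
            "postnorm_mean": report["summaries"][f"{feature}/postnorm"]["whole_brain_mean"],
            "mean_diff": res["mean_diff_prenorm_minus_postnorm"],
            "paired_t": res["wholebrain_t"],
            "paired_p": res["wholebrain_p"],
            "cv_median_prenorm": report["summaries"][f"{feature}/prenorm"]["cv"]["median"],
            "cv_median_postnorm": report["summaries"][f"{feature}/postnorm"]["cv"]["median"],
        })
    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)

    for _, r in df.iterrows():
        arrow = "higher" if r.mean_diff > 0 else "lower"
        print(f"{r.feature:>4}: Prenorm {arrow} than Postnorm "
              f"({r.prenorm_mean:.4g} vs {r.postnorm_mean:.4g}, "
              f"t={r.paired_t:.1f}, p={r.paired_p:.2g})")
    print("self-check:", json.dumps(report["self_check"]))
    print(f"DMN mask (positive-FC union, FDR): {report['dmn_mask_voxels']} voxels")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
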