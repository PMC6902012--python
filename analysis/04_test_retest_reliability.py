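#!/usr/bin/env python
"""Test-retest reliability (two-session ICC) under the two normalization orders.

Simulates two-session cohorts with genuine subject-level signal (between-
subject tSNR SD 15, within-subject SD 3) and per-scan warps, computes
voxelwise ICC = (Vb - Vw)/(Vb + Vw) for tSNR and ALFF under each order, and
repeats over seeded replicates.  Prenorm's warp-dependent noise suppression
varies between a subject's scans, loading the within-subject variance and
dragging its ICC down; Postnorm leaves the feature values (hence reliability)
intact.

Writes results/04_icc_reliability.csv.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from normcomp import reliability_study_config, run_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--replicates", type=int, default=5)
    ap.add_argument("--out", type=Path, default=Path("results/04_icc_reliability.csv"))
    args = ap.parse_args()

    rows = []
    for rep in range(args.replicates):
        cfg = reliability_study_config(seed=args.seed + rep)
        cfg = dataclasses.replace(cfg, features=("tsnr", "alff"), network_signal=None)
        report = run_study(cfg)
        for key, entry in report["icc"].items():
            feature, strategy = key.split("/")
            rows.append({
                "replicate": rep, "feature": feature, "strategy": strategy,
                "median_icc": entry["median"],
                **{f"band_{k}": v for k, v in entry["bands"].items()},
            })
    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)

    pivot = df.pivot_table(index="feature", columns="strategy", values="median_icc")
    print(f"median voxelwise ICC over {args.replicates} replicates "
          "(average of per-replicate medians):")
    print(pivot.round(3).to_string())
    for feature in pivot.index:
        diff = pivot.loc[feature, "postnorm"] - pivot.loc[feature, "prenorm"]
        print(f"{feature}: Postnorm median ICC exceeds Prenorm by {diff:.3f}")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
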