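#!/usr/bin/env python
"""Validate the universal (uncalibrated) model on the simulated cohort.

Scores the analysis sample with the illustrative non-laboratory model
and reports discrimination (Harrell's C) and calibration (P/O ratio,
Nam-D'Agostino) per region and overall, before any recalibration.
Expect clear regional spread in C and systematic underestimation where
regional hazards exceed the model's reference.
"""

import argparse
from pathlib import Path

import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cvdrecal.cohort import first_event_outcome, read_cohort
from cvdrecal.metrics import calibration_table, harrell_c, nam_dagostino, po_ratio
from cvdrecal.risk import default_model, score_cohort

import pandas as pd


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort/cohort.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/universal"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cohort = read_cohort(args.cohort).reset_index(drop=True)
    preds = score_cohort(cohort, default_model())
    outcome = first_event_outcome(cohort, "total_cvd")

    rows = []
    for sex in ("female", "male"):
        for region in ["overall"] + sorted(cohort.region_id.unique()):
            m = (cohort.sex == sex).to_numpy()
            if region != "overall":
                m &= (cohort.region_id == region).to_numpy()
            t, e, p = outcome["time"][m], outcome["event"][m], preds["p_total"][m]
            c = harrell_c(t, e, p)
            nd = nam_dagostino(calibration_table(t, e, p))
            rows.append(
                dict(region=region, sex=sex, n=int(m.sum()), events=int(e.sum()),
                     c=c.c, c_lo=c.ci_lo, c_hi=c.ci_hi,
                     po_ratio=po_ratio(t, e, p), nd_chi2=nd.chi2, nd_p=nd.p_value)
            )
    metrics = pd.DataFrame(rows)
    metrics.to_csv(args.out_dir / "metrics_uncalibrated.csv", index=False)

    ov = metrics[metrics.region == "overall"]
    print("overall performance of the universal model (uncalibrated):")
    print(ov[["sex", "n", "events", "c", "po_ratio", "nd_chi2"]].to_string(index=False))
    reg = metrics[metrics.region != "overall"]
    print(f"\nregional C spread: {reg.c.min():.3f}-{reg.c.max():.3f}; "
          f"P/O spread: {reg.po_ratio.min():.2f}-{reg.po_ratio.max():.2f}")
    print(f"wrote {args.out_dir/'metrics_uncalibrated.csv'}")


if __name__ == "__main__":
    main()
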