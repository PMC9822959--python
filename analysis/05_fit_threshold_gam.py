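#!/usr/bin/env python
"""Temperature flag -- SST threshold in the stock-recruitment relationship.

Fits the threshold GAM (separate recruitment-on-SSB smooths below/above a
candidate SST threshold, threshold by GCV over the 0.2-0.8 SST quantile
range), runs the LOOCV competition against the plain GAM, and applies the
three acceptance criteria (regime edfs differ, a significant regime slope,
a deep GCV valley).
"""

import argparse
from pathlib import Path

import pandas as pd

from stockshift.io import align_srr, read_sst_csv, read_stock_csv
from stockshift.tgam import decide_tgam


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for label in ("effects", "null"):
        series = read_stock_csv(args.data_dir / f"stock_{label}.csv", recruitment_age=1)
        env = read_sst_csv(args.data_dir / f"sst_{label}.csv")
        dec = decide_tgam(align_srr(series), env, lazy_loocv=False)
        fit = dec.details.pop("fit")
        print(
            f"{label}: verdict {dec.verdict}"
            + (f", threshold {dec.threshold:.2f} degC" if dec.threshold else "")
            + f"; edf {fit.edf_below:.2f}/{fit.edf_above:.2f}, criteria {dec.criteria}"
        )
        pd.DataFrame(fit.gcv_profile, columns=["sst_threshold", "gcv"]).to_csv(
            args.out_dir / f"gcv_profile_{label}.csv", index=False
        )
        rows.append(
            {
                "stock": label,
                "verdict": dec.verdict,
                "threshold_degC": dec.threshold,
                "edf_below": fit.edf_below,
                "edf_above": fit.edf_above,
                "slope_p_below": fit.slope_p_below,
                "slope_p_above": fit.slope_p_above,
                "loocv_prefers_tgam": dec.loocv_prefers_tgam,
                **{f"criterion_{k}": v for k, v in dec.criteria.items()},
            }
        )
    pd.DataFrame(rows).to_csv(args.out_dir / "tgam_decision.csv", index=False)
    print(f"wrote tgam_decision.csv and GCV profiles to {args.out_dir}")


if __name__ == "__main__":
    main()
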