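#!/usr/bin/env python
"""Generate the two study stocks and write them as assessment-style CSVs.

The *all-effects* stock carries every regime-shift signature at once: an
F ramp across the Allee fold (abrupt SSB collapse and recovery, a closed
hysteresis loop) and an SST-switched stock-recruitment relationship under a
warming trend.  The *null* stock is the matched control: reversible logistic
dynamics under gently varying F, one stationary Ricker SRR, SST without
effect.  Ground truth (fold levels, SST threshold, SRR parameters) goes to a
JSON side file so later steps can score themselves.
"""

import argparse
import json
from pathlib import Path

from stockshift.io import write_sst_csv, write_stock_csv
from stockshift.pipeline import _jsonify
from stockshift.simulate import simulate_diagnostic_stock


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    for label, effects in (("effects", True), ("null", False)):
        series, env, truth = simulate_diagnostic_stock(seed=args.seed, with_effects=effects)
        write_stock_csv(series, args.out_dir / f"stock_{label}.csv")
        write_sst_csv(env, args.out_dir / f"sst_{label}.csv")
        (args.out_dir / f"truth_{label}.json").write_text(
            json.dumps(
                _jsonify(
                    {
                        "collapse_F": truth.collapse_F,
                        "recovery_F": truth.recovery_F,
                        "sst_threshold": truth.true_sst_threshold,
                        "srr_params": truth.true_srr_params,
                        "seed": truth.seed,
                        "extras": truth.extras,
                    }
                ),
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        print(
            f"{label}: {len(series)} years, SSB range "
            f"{series.ssb[~(series.ssb != series.ssb)].min():.0f}-{series.ssb.max():.0f} t"
            + (f", fold at F={truth.collapse_F:.3f}/{truth.recovery_F:.3f}" if effects else "")
        )
    print(f"wrote stock/SST CSVs and truth JSONs to {args.out_dir}")


if __name__ == "__main__":
    main()
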