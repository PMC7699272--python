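#!/usr/bin/env python
"""Collagen-PET quantification: lung %ID, compartments and border rings.

Runs the pipeline for the bleomycin animal and a seed-matched saline control
and compares total-lung uptake per day, then inspects the distance-ring
profile around the day-28 lesions.  Expected behaviour: bleomycin lungs
accumulate more tracer than controls at every post-challenge day, and the
ring profile peaks in the first shell outside the MRI-defined lesion.
"""

import argparse
from pathlib import Path

import pandas as pd

from fibroquant import PipelineConfig
from fibroquant.pipeline import run_pipeline

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    runs = {}
    for name, control in (("bleomycin", False), ("control", True)):
        cfg = PipelineConfig(seed=args.seed, control=control,
                             outdir=str(RESULTS / f"run_{name}"))
        runs[name] = run_pipeline(cfg)

    up_b = pd.read_csv(runs["bleomycin"] / "pet_uptake.csv")
    up_c = pd.read_csv(runs["control"] / "pet_uptake.csv")
    lung_b = up_b[up_b.compartment == "total_lung"].set_index("day")["percent_id"]
    lung_c = up_c[up_c.compartment == "total_lung"].set_index("day")["percent_id"]
    cmp = pd.DataFrame({"bleomycin_%ID": lung_b, "control_%ID": lung_c,
                        "ratio": lung_b / lung_c}).round(3)
    cmp.to_csv(RESULTS / "lung_uptake_comparison.csv")
    print("total-lung %ID per day:")
    print(cmp.to_string())
    sep = (cmp.loc[cmp.index > 0, "ratio"] > 1).all()
    print(f"bleomycin > control at all post-challenge days: {sep}")

    rings = pd.read_csv(runs["bleomycin"] / "pet_rings.csv")
    d28 = rings[rings.day == 28]
    best = d28.loc[d28["mean_activity_bq_ml"].idxmax(), "ring"]
    print(f"day-28 ring profile argmax: ring {best:+d} "
          "(0 = first shell outside the lesion)")
    print(d28[["ring", "mean_activity_bq_ml", "percent_id"]].round(2).to_string(index=False))


if __name__ == "__main__":
    main()
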