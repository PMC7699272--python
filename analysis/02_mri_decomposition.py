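#!/usr/bin/env python
"""Dual-echo decomposition of the bleomycin series: edema vs. tissue curves.

Runs the full MRI analysis pipeline on the default bleomycin phantom and
writes the compartment report and the estimate-vs-truth recovery table to
results/.  The headline readouts are the timing of the two volume peaks:
edema (long-echo lesion signal) should peak at day 7 and fibrotic tissue
(short-minus-long residue) at day 28.
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

    cfg = PipelineConfig(seed=args.seed, outdir=str(RESULTS / "run_bleomycin"))
    rundir = run_pipeline(cfg)
    rec = pd.read_csv(rundir / "recovery_report.csv").set_index("day")

    print(f"pipeline outputs under {rundir}")
    print(rec[["edema_volume_true_mm3", "edema_volume_est_mm3",
               "tissue_volume_true_mm3", "tissue_volume_est_mm3",
               "edema_dice", "tissue_dice"]].round(1).to_string())
    print(f"estimated edema peak day:  {rec['edema_volume_est_mm3'].idxmax()}")
    print(f"estimated tissue peak day: {rec['tissue_volume_est_mm3'].idxmax()}")
    worst = rec.loc[rec.index > 0, ["edema_dice", "tissue_dice"]].min().min()
    print(f"worst per-compartment Dice across diseased days: {worst:.3f}")


if __name__ == "__main__":
    main()
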