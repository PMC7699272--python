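# fibroquant

Quantitative image analysis for the bleomycin rat model of pulmonary
fibrosis: dual-echo UTE-MRI lesion decomposition into inflammatory
("edema") and fibrotic ("tissue") compartments, percent-injected-dose
(%ID) quantification of a collagen-binding PET tracer in MRI-derived ROIs,
comparative-CT (ΔΔCT) gene-expression analysis, and the three-family
significance-symbol reporting used for longitudinal preclinical readouts.

Because no imaging data are deposited for this model, the package ships a
first-class digital-phantom module: seeded 3-D rat-thorax label maps with
patchy lung lesions that follow the disease trajectory (edema peaking at
day 7 after challenge, fibrotic tissue at day 28), simulated UTE echoes at
TE = 0.324 ms and 1 ms, and a PET frame with tracer concentrated in the
one-voxel "active border" of parenchyma around each lesion. Every analysis
can therefore be validated against known ground truth.

## The method in brief

**MRI decomposition.** At ultra-short echo time (TE_short = 0.324 ms) both
fluid and fibrotic tissue are bright inside the dark aerated lung; at
TE_long = 1 ms only long-T2* fluid signal survives
(S = PD · e^(−TE/T2*)). Lesions are extracted per echo as the high-signal
area inside the lung ROI by histogram thresholding, vessels are
subtracted, and

    edema  = lesion(TE_long)  \ vessels
    tissue = (lesion(TE_short) \ vessels) \ lesion(TE_long)

**PET quantification.** MRI ROIs are transferred to the PET grid by
fractional-occupancy resampling (≥ 0.5 rule) and uptake is reported as
%ID = 100 · Σ(C·v) / D for activity concentration C, voxel volume v and
injected dose D (35 ± 5 MBq Cu-64, t½ = 12.7 h, scan 1 h post-injection;
decay-corrected values are emitted alongside). Border localisation is
profiled by binning the signed Euclidean distance to the lesion boundary
into concentric rings.

**ΔΔCT.** Target CTs are normalised per sample against the mean CT of the
B2M/RLP13a reference pair (the geometric mean on the expression scale),
calibrated against same-day control means, and reported as 2^−ΔΔCT.

**Statistics.** One-way ANOVA with Bonferroni-adjusted pairwise post-hoc
tests (or Mann–Whitney), annotated with */#/§ glyphs at the p < 0.05 /
0.01 / 0.001 / 0.0001 tiers for the three comparison families
(vs. same-day control / between bleomycin days / vs. baseline).

## Worked example

```python
from fibroquant import PipelineConfig
from fibroquant.pipeline import run_pipeline
import pandas as pd

rundir = run_pipeline(PipelineConfig(seed=1, outdir="results/run_bleomycin"))
rec = pd.read_csv(rundir / "recovery_report.csv").set_index("day")
print(rec[["edema_volume_true_mm3", "edema_volume_est_mm3",
           "tissue_volume_true_mm3", "tissue_volume_est_mm3"]].round(1))
```

prints (default desk-scale conditions: 96³ grid at 0.6 mm, SNR 20):

```
     edema_volume_true_mm3  edema_volume_est_mm3  tissue_volume_true_mm3  tissue_volume_est_mm3
day
0                      0.0                   0.0                     0.0                    0.0
7                    800.1                 791.6                   100.0                  101.1
14                   500.0                 489.9                   249.9                  238.0
21                   300.0                 289.2                   400.0                  384.7
28                   200.0                 192.0                   500.0                  469.8
```

i.e. the recovered edema curve peaks at day 7 and the tissue curve at
day 28, each within a few percent of the phantom's ground-truth volumes.
The same run writes `pet_uptake.csv` (total-lung %ID rising from 0.52 at
baseline to 1.75 at day 28, versus ≈ 0.5 in a seed-matched control) and
`pet_rings.csv` (uptake maximal in ring 0, the first shell outside the
lesion).

The numbered scripts under `analysis/` run the same steps as a narrated
study — `01_simulate_phantoms.py` through `05_group_stats.py` — writing
their tables under `results/`.

There is also a CLI: `fibroquant simulate|mri|pet|ddct|stats|run`
(see `fibroquant --help`).

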