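# Methods

## The model system

Intratracheal bleomycin in the rat produces acute, patchy lung
inflammation during the first week that remodels into patchy fibrosis over
weeks three to four. The package quantifies this course from three
readouts: dual-echo UTE MRI (lesion volumes split into a fluid-rich
inflammatory compartment and a fibrotic one), static PET of a
collagen-binding tracer (uptake as percent injected dose, concentrated at
the rim of actively remodelling lesions), and qPCR panels quantified by
the comparative-CT method.

## Digital thorax phantom

The phantom is the package's ground-truth engine, not a test fixture: a
label map assigns each voxel one of seven classes (background,
muscle/organ, lung parenchyma, vessel, edema, fibrotic tissue, active
border) on a configurable grid. Defaults are a 96³ grid at 0.6 mm — a
desk-scale stand-in for the 58 mm field of view at a 192 × 192 in-plane
matrix (≈ 0.30 mm), which remains available by configuration — and a
0.4 mm isotropic PET grid.

Anatomy is an ellipsoidal body with two ellipsoidal lung fields and 2–6
cylindrical vessels, all jittered per seed. Lesions are drawn from two
smooth Gaussian-filtered random fields (correlation length ≈ 1.2 mm),
fixed per seed: the fibrotic compartment is the top-n set of a "fibrosis"
potential, edema the top-n set of a correlated "inflammation" potential
among the remaining lung voxels. Because the fields are day-independent,
one seed yields one animal whose lesions wax and wane coherently along the
trajectory, and each compartment volume matches its daily target to within
half a voxel. Correlating the two fields (0.6 shared weight) makes
fibrotic patches cluster near inflamed regions without reducing either
compartment to a thin shell of the other, which keeps both compartments
mm-scale blobs as in the modelled disease. The active border is the
one-voxel 6-connected shell of parenchyma around any lesion voxel,
matching the one-ring morphology used by the PET ring analysis.

The default longitudinal targets are edema (0, 800, 500, 300, 200) mm³
and fibrotic tissue (0, 100, 250, 400, 500) mm³ on days (0, 7, 14, 21,
28): a day-7 edema peak and a day-28 tissue peak with a baseline of zero.
`TrajectorySpec` validates these shape constraints; a lesion-free control
trajectory is provided for the saline arm.

### Signal models

MRI: noise-free signal is mono-exponential, S = PD·exp(−TE/T2*), with
per-class proton densities (a.u.) lung 15, muscle 80, vessel 100, edema
95, fibrotic 70 and T2* (ms) lung 0.5, muscle 8, vessel 20, edema 15,
fibrotic 0.7. The fibrotic T2* sits between the two echo times, so
fibrotic voxels lose ≈ 62 % of their signal between echoes while fluid
classes lose < 7 %; that contrast is what the ROI subtraction exploits.
Noise is Rician (magnitude of complex Gaussian). The SNR knob is defined
against the short-echo edema signal; SNR 20 is the default study
condition. No partial-volume, bias-field or motion effects are simulated —
the analysis operates on reconstructed magnitude images, and scanner
physics is out of scope.

PET: relative per-class uptake densities are background 0, parenchyma
0.15, muscle 0.30, vessel 0.40, edema 0.25, fibrotic 0.35 and active
border 6.0 (scaled per day by the border-uptake curve, rising to 1.0 at
day 28). The lesion core is deliberately colder than the border: the
tracer binds non-cross-linked collagen at the remodelling rim, not the
established lesion. Absolute scale is set by a calibration factor mapping
relative density to MBq; a series calibrates it once on the day-0 healthy
anatomy so that the baseline lung holds a configurable fraction (default
0.5 %) of the injected dose — later days then accumulate activity on top,
which is what separates bleomycin animals from controls. Concentration is
rebinned to the PET grid by exact volume-weighted overlap (conserving
total activity to machine precision), blurred with a 0.8 mm FWHM Gaussian
PSF, and Poisson-perturbed at a default 10⁷ expected counts/MBq per voxel.
Injected dose is drawn uniformly from 30–40 MBq and the
injection-to-scan delay from 55–65 min per session; the Cu-64 half-life is
12.7 h.

## MRI decomposition

The lung ROI is taken as given when supplied (the analogue of semi-manual
contouring; phantom truth in the pipeline) or segmented automatically:
Otsu on the short echo finds the bright body, the filled body envelope
minus the bright voxels gives candidate dark regions, the two largest
connected components are kept and hole-filled (Dice ≥ 0.96 against phantom
truth in practice).

Lesion extraction thresholds the within-lung histogram per echo
(each echo against its own histogram). Three rules are available:

* `mode_fraction` (default): threshold = background mode + 0.3 × (P99.5 −
  mode). The robust high percentile is anchored by vessels (always bright
  and present in lung at both echoes), which places the cut well above the
  aerated-lung noise floor and below every lesion class at both echoes.
  The simpler mode-plus-k·MAD rule fails specifically at the long echo,
  where the fibrotic class (≈ 17 a.u.) sits only ≈ 2.5 noise SD above the
  noise floor: a 4·MAD cut lands on top of the fibrotic signal and
  misassigns roughly half of it to the fluid compartment, so the
  dynamic-range rule was made the default.
* `mode_mad`: mode + 4 × 1.4826 × MAD, retained as an alternative.
* `otsu`: Otsu's criterion within the lung; appropriate when a strong
  bimodal histogram is guaranteed.

Voxels strictly above the threshold form the lesion mask (ties excluded);
connected components under 5 voxels are discarded as noise (configurable,
disable-able). Vessels are subtracted as an explicit mask — phantom truth
or user-drawn; no tubularity heuristic is invented. The compartments are
pure ROI set algebra: edema = lesion_long \ vessels, tissue =
(lesion_short \ vessels) \ lesion_long, which makes them disjoint by
construction and idempotent under re-application. A voxelwise
signal-difference variant was considered and rejected as the default
because the compartment definition in use is a region difference, not an
intensity difference.

## PET quantification

ROIs move from the MRI to the PET grid by fractional-occupancy
resampling: the mask indicator is rebinned with the exact overlap weights
and voxels with occupancy ≥ 0.5 are kept. On identical grids this is the
identity; under an optional user-supplied rigid transform the indicator is
resampled linearly (SimpleITK) before the same cut. No automatic
registration is attempted — phantom frames are co-simulated, and
registration is out of scope.

%ID(mask) = 100 · Σ_mask C·v / D. It is additive over disjoint masks and,
for the noiseless PSF-free phantom on the simulation grid, recovers the
configured lung dose fraction to < 10⁻⁶ relative error (the conservation
oracle). Decay correction scales activity by 2^(Δt/t½) with Δt measured
from the reference time (default: injection) to the scan; because the
modelled data are a single static frame, both raw and decay-corrected %ID
are reported and no kinetic modelling is attempted.

The ring profile bins the signed Euclidean distance to the lesion
boundary into shells of width 0.8 mm (two PET voxels) by default, five
rings in and out, clipped to the lung; ring 0 is the first shell outside
the lesion, so border-localised uptake shows as an argmax at ring 0/+1.
The "surrounding" compartment is the whole lung minus both per-echo lesion
ROIs; rings provide the margin-resolved alternative.

## Comparative CT

ΔCT subtracts the arithmetic mean of the two reference-gene CTs — the
geometric mean of reference expression on the 2^−CT scale — and ΔΔCT
subtracts the mean control ΔCT for the same gene and day (with 4–5
controls per day, the mean is the natural calibrator; per-sample pairing
is not modelled). Fold change is 2^−ΔΔCT with efficiency fixed at 2.
Summaries report mean ± SEM on the fold-change scale, with the log-scale
ΔΔCT mean and SEM alongside. Note the exact-normalisation property lives
on the log scale: the control-group mean ΔΔCT is 0 (geometric-mean fold
change 1) by construction, while the arithmetic mean of control fold
changes exceeds 1 by Jensen's inequality.

## Statistics and symbols

Comparisons delegate to scipy (two-sample t-tests under the
ANOVA/Bonferroni convention, with the Bonferroni factor equal to the
number of comparisons in the family; exact/asymptotic Mann–Whitney as the
non-parametric path — both offered because longitudinal preclinical
studies commonly mix them, and the choice is recorded in the output).
Symbols are a pure lookup: 1–4 glyphs of the family's character at p <
0.05/0.01/0.001/0.0001, empty at p ≥ 0.05. A vectorised null simulation
(10,000 two-sample t-tests at n = 6/6) verifies the 0.05-tier false-positive
rate sits at the nominal level.

## Numerical choices and reproducibility

* All randomness flows through `numpy.random.SeedSequence([seed, key])`
  fan-out, so stages are individually reproducible and identical seeds
  give bit-identical volumes; derived seeds stay below 2³¹.
* Mask resampling and activity rebinning share one exact 1-D
  interval-overlap kernel (axis-aligned grids factorise), so conservation
  holds to floating-point precision rather than approximately.
* Thresholding uses strict inequality; argpartition top-n selection on
  continuous fields makes volume targeting exact to half a voxel with
  measure-zero tie probability.
* Degenerate inputs fail loudly: constant within-lung histograms, empty
  lung masks, empty lesions for ring profiles, unknown class ids,
  non-covering PET grids, missing reference genes and missing controls all
  raise informative errors.

## Problem sizes

Tests and the acceptance script run the desk-scale conditions: 96³ MRI
phantoms (0.6 mm), 144³ PET grids (0.4 mm), ten seeds for the
peak-timing and border-localisation sweeps, and 10,000 replicates for the
null calibration. Unit tests use 48³/64³ phantoms where the property under
test does not depend on resolution.

## Known limitations

* The phantom has no partial-volume mixing at MRI resolution, no
  respiratory motion, no attenuation/scatter physics and no k-space or
  radial-reconstruction effects; passing recovery tests therefore bound
  algorithmic correctness, not scanner-level robustness.
* The automatic lung segmentation is a surrogate for manual contouring
  and is validated only on phantom anatomy.
* Vessel identification is taken as input; real data would need a vessel
  mask from contouring or an external filter.
* PET noise is voxelwise Poisson on the reconstructed grid, which
  understates the correlated noise of iterative reconstructions.
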