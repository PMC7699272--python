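"""Digital rat-thorax phantoms for dual-echo UTE-MRI and collagen-PET.

The phantom emulates the bleomycin lung-injury model: an ellipsoidal body with
two aerated lung fields, a handful of intrapulmonary vessels, and patchy
lesions with two components — a fluid-rich inflammatory ("edema") compartment
with long T2*, visible at both echo times, and a fibrotic ("tissue")
compartment with sub-millisecond T2*, visible only at the short echo.  A
collagen-binding PET tracer accumulates preferentially in a one-voxel shell of
parenchyma around the lesions (the "active border"), mirroring uptake at the
rim of actively remodelling fibrosis rather than in the lesion core.

Longitudinal series follow the disease trajectory of the model: edema volume
peaks around day 7 (acute inflammation) and fibrotic-tissue volume around
day 28.  All randomness is driven by explicit integer seeds; identical
arguments reproduce bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridSpec, resample_intensive

__all__ = [
    "TissueClass",
    "TissueProperties",
    "TrajectorySpec",
    "EchoPair",
    "PetVolume",
    "DayRecord",
    "PhantomSeries",
    "make_label_map",
    "simulate_echo",
    "simulate_echo_pair",
    "simulate_pet",
    "make_series",
    "lung_region_mask",
    "sigma_for_snr",
    "TE_SHORT_MS",
    "TE_LONG_MS",
    "CU64_HALF_LIFE_HOURS",
]

TE_SHORT_MS = 0.324
TE_LONG_MS = 1.0
CU64_HALF_LIFE_HOURS = 12.7


class TissueClass(IntEnum):
    """Fixed voxel-class enumeration of the phantom label map."""

    BACKGROUND = 0
    MUSCLE_ORGAN = 1
    LUNG_PARENCHYMA = 2
    VESSEL = 3
    EDEMA = 4
    FIBROTIC_TISSUE = 5
    ACTIVE_BORDER = 6


#: Classes that make up the anatomical lung region (the "Lung-ROI" truth).
LUNG_REGION_CLASSES = (
    TissueClass.LUNG_PARENCHYMA,
    TissueClass.VESSEL,
    TissueClass.EDEMA,
    TissueClass.FIBROTIC_TISSUE,
    TissueClass.ACTIVE_BORDER,
)

LESION_CLASSES = (TissueClass.EDEMA, TissueClass.FIBROTIC_TISSUE)


def lung_region_mask(labels: np.ndarray) -> np.ndarray:
    """Boolean mask of the whole lung region (parenchyma + vessels + lesions)."""
    return np.isin(labels, LUNG_REGION_CLASSES)


@dataclass(frozen=True)
class TissueProperties:
    """Per-class signal and uptake properties of the phantom.

    ``proton_density`` is in arbitrary signal units, ``t2_star`` in ms, and
    ``pet_uptake_density`` in relative activity per unit volume (the absolute
    Bq scale is set at simulation time from the injected dose).  The defaults
    place the fibrotic T2* between the two echo times so fibrotic voxels fade
    between echoes while fluid-like classes (vessel, edema) do not, and give
    the active border by far the highest tracer density among lung classes.
    """

    proton_density: dict[TissueClass, float] = field(
        default_factory=lambda: {
            TissueClass.BACKGROUND: 0.0,
            TissueClass.MUSCLE_ORGAN: 80.0,
            TissueClass.LUNG_PARENCHYMA: 15.0,
            TissueClass.VESSEL: 100.0,
            TissueClass.EDEMA: 95.0,
            TissueClass.FIBROTIC_TISSUE: 70.0,
            TissueClass.ACTIVE_BORDER: 15.0,
        }
    )
    t2_star: dict[TissueClass, float] = field(
        default_factory=lambda: {
            TissueClass.BACKGROUND: 1.0,
            TissueClass.MUSCLE_ORGAN: 8.0,
            TissueClass.LUNG_PARENCHYMA: 0.5,
            TissueClass.VESSEL: 20.0,
            TissueClass.EDEMA: 15.0,
            TissueClass.FIBROTIC_TISSUE: 0.7,
            TissueClass.ACTIVE_BORDER: 0.5,
        }
    )
    pet_uptake_density: dict[TissueClass, float] = field(
        default_factory=lambda: {
            TissueClass.BACKGROUND: 0.0,
            TissueClass.MUSCLE_ORGAN: 0.30,
            TissueClass.LUNG_PARENCHYMA: 0.15,
            TissueClass.VESSEL: 0.40,
            TissueClass.EDEMA: 0.25,
            TissueClass.FIBROTIC_TISSUE: 0.35,
            TissueClass.ACTIVE_BORDER: 6.0,
        }
    )

    def __post_init__(self) -> None:
        for cls in TissueClass:
            for table, name in (
                (self.proton_density, "proton_density"),
                (self.t2_star, "t2_star"),
                (self.pet_uptake_density, "pet_uptake_density"),
            ):
                if cls not in table:
                    raise ValueError(f"{name} missing class {cls.name}")
            if self.t2_star[cls] <= 0:
                raise ValueError(f"t2_star must be positive for {cls.name}")

    def lut(self, table: dict[TissueClass, float]) -> np.ndarray:
        """Dense lookup table indexed by class id."""
        out = np.zeros(max(TissueClass) + 1)
        for cls, v in table.items():
            out[int(cls)] = v
        return out


@dataclass(frozen=True)
class TrajectorySpec:
    """Longitudinal disease trajectory: target lesion volumes per imaging day.

    ``edema_volume_curve`` and ``tissue_volume_curve`` give target compartment
    volumes in mm^3 for each entry of ``days``; ``border_uptake_curve`` scales
    the active-border tracer density per day (relative units).  The defaults
    encode the bleomycin model: edema peaks at day 7, fibrotic tissue at
    day 28, and border activity rises slowly as fibrosis matures.
    """

    days: tuple[int, ...] = (0, 7, 14, 21, 28)
    edema_volume_curve: tuple[float, ...] = (0.0, 800.0, 500.0, 300.0, 200.0)
    tissue_volume_curve: tuple[float, ...] = (0.0, 100.0, 250.0, 400.0, 500.0)
    border_uptake_curve: tuple[float, ...] = (0.0, 0.6, 0.8, 0.9, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.days)
        for name in ("edema_volume_curve", "tissue_volume_curve", "border_uptake_curve"):
            curve = getattr(self, name)
            if len(curve) != n:
                raise ValueError(f"{name} must have one value per day")
            if any(v < 0 for v in curve):
                raise ValueError(f"{name} must be nonnegative")
        if 0 not in self.days:
            raise ValueError("trajectory must include a day-0 baseline")
        i0 = self.days.index(0)
        if self.edema_volume_curve[i0] != 0 or self.tissue_volume_curve[i0] != 0:
            raise ValueError("day-0 lesion volumes must be zero")
        if any(self.edema_volume_curve) and 7 in self.days:
            peak = self.days[int(np.argmax(self.edema_volume_curve))]
            if peak != 7:
                raise ValueError(f"edema volume must peak at day 7, peaks at {peak}")
        if any(self.tissue_volume_curve) and 28 in self.days:
            peak = self.days[int(np.argmax(self.tissue_volume_curve))]
            if peak != 28:
                raise ValueError(f"tissue volume must peak at day 28, peaks at {peak}")

    @classmethod
    def control(cls, days: tuple[int, ...] = (0, 7, 14, 21, 28), seed: int = 0
                ) -> "TrajectorySpec":
        """Lesion-free saline-control trajectory (all curves zero)."""
        z = tuple(0.0 for _ in days)
        return cls(days=days, edema_volume_curve=z, tissue_volume_curve=z,
                   border_uptake_curve=z, seed=seed)

    def at(self, day: int) -> tuple[float, float, float]:
        """(edema mm^3, tissue mm^3, border uptake scale) targets for a day."""
        if day not in self.days:
            raise ValueError(
                f"day {day} not in trajectory; valid days are {list(self.days)}"
            )
        i = self.days.index(day)
        return (
            self.edema_volume_curve[i],
            self.tissue_volume_curve[i],
            self.border_uptake_curve[i],
        )


@dataclass(frozen=True)
class TissueLabelMap:
    """Phantom ground truth: one :class:`TissueClass` id per voxel."""

    grid: GridSpec
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.grid.check_array(self.labels, "labels")

    def volume_mm3(self, cls: TissueClass) -> float:
        return float(np.count_nonzero(self.labels == cls)) * self.grid.voxel_volume

    def mask(self, cls: TissueClass) -> np.ndarray:
        return self.labels == int(cls)


@dataclass(frozen=True)
class EchoPair:
    """Two co-registered UTE volumes at the short and long echo time."""

    grid: GridSpec
    te_short_image: np.ndarray
    te_long_image: np.ndarray
    te_short_ms: float = TE_SHORT_MS
    te_long_ms: float = TE_LONG_MS

    def __post_init__(self) -> None:
        self.grid.check_array(self.te_short_image, "te_short_image")
        self.grid.check_array(self.te_long_image, "te_long_image")


@dataclass(frozen=True)
class PetVolume:
    """Static PET frame: activity concentration plus dosimetry metadata."""

    grid: GridSpec
    activity_concentration: np.ndarray  # Bq/mL per voxel
    injected_dose_mbq: float
    delay_minutes: float = 60.0
    half_life_hours: float = CU64_HALF_LIFE_HOURS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid.check_array(self.activity_concentration, "activity_concentration")
        if self.injected_dose_mbq <= 0:
            raise ValueError("injected_dose_mbq must be positive")
        if self.half_life_hours <= 0:
            raise ValueError("half_life_hours must be positive")
        if np.any(self.activity_concentration < 0):
            raise ValueError("activity concentration must be nonnegative")


# --------------------------------------------------------------------------
# geometry helpers


def _ellipsoid(grid: GridSpec, center_mm, semiaxes_mm) -> np.ndarray:
    coords = np.meshgrid(*(grid.centers(a) for a in range(3)), indexing="ij")
    q = sum(
        ((c - mu) / ax) ** 2 for c, mu, ax in zip(coords, center_mm, semiaxes_mm)
    )
    return q <= 1.0


def _vessel_mask(
    grid: GridSpec, lung: np.ndarray, rng: np.random.Generator, n_vessels: int
) -> np.ndarray:
    """Cylindrical vessels: random lines through the lung fields."""
    idx = np.argwhere(lung)
    pts = (idx + 0.5) * np.asarray(grid.spacing) + np.asarray(grid.origin)
    vessels = np.zeros(grid.shape, dtype=bool)
    # split the lung voxels into left/right fields by the x median so vessels
    # alternate between the two lungs
    x_mid = np.median(pts[:, 0])
    for k in range(n_vessels):
        side = pts[:, 0] > x_mid if k % 2 else pts[:, 0] <= x_mid
        sub = pts[side]
        anchor = sub[rng.integers(len(sub))]
        direction = np.array([rng.normal(0, 0.25), rng.normal(0, 0.25), 1.0])
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(0.7, 1.2)
        d = pts - anchor
        perp = d - np.outer(d @ direction, direction)
        hit = np.einsum("ij,ij->i", perp, perp) <= radius**2
        vessels[tuple(idx[hit].T)] = True
    return vessels


_SIX_CONN = ndimage.generate_binary_structure(3, 1)


def make_label_map(
    grid: GridSpec,
    trajectory: TrajectorySpec,
    day: int,
    seed: int,
) -> TissueLabelMap:
    """Generate the seeded thorax label map for one imaging day.

    Anatomy (body, lung fields, vessels) and two correlated smooth random
    "potential" fields depend only on ``seed``, so a longitudinal series of
    calls with one seed shows the same animal with lesions waxing and waning
    along the trajectory.  The fibrotic compartment at each day is the
    top-``n`` set of the fibrosis potential restricted to eligible lung
    voxels, and edema the top set of the (correlated) inflammation potential
    among the remaining voxels, each ``n`` matching the day's volume target
    to within half a voxel volume — so each compartment is a patchy union of
    mm-scale blobs, fibrotic streaks clustering near the inflammatory
    regions.  The active border is the one-voxel 6-connected shell of
    parenchyma around any lesion voxel.
    """
    edema_mm3, tissue_mm3, _ = trajectory.at(day)

    geo_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    field_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))

    half = [0.5 * n * s for n, s in zip(grid.shape, grid.spacing)]
    center = [o + h for o, h in zip(grid.origin, half)]

    labels = np.zeros(grid.shape, dtype=np.uint8)
    body_ax = [h * f * geo_rng.uniform(0.97, 1.03) for h, f in zip(half, (0.84, 0.80, 0.96))]
    body = _ellipsoid(grid, center, body_ax)
    labels[body] = TissueClass.MUSCLE_ORGAN

    lungs = np.zeros(grid.shape, dtype=bool)
    for sign in (-1.0, +1.0):
        c = [
            center[0] + sign * 0.36 * half[0] * geo_rng.uniform(0.95, 1.05),
            center[1] + 0.02 * half[1] * geo_rng.normal(),
            center[2] + 0.02 * half[2] * geo_rng.normal(),
        ]
        ax = [h * f * geo_rng.uniform(0.95, 1.05) for h, f in zip(half, (0.30, 0.40, 0.58))]
        lungs |= _ellipsoid(grid, c, ax)
    lungs &= body
    labels[lungs] = TissueClass.LUNG_PARENCHYMA

    n_vessels = int(geo_rng.integers(2, 7))
    vessels = _vessel_mask(grid, lungs, geo_rng, n_vessels)
    labels[vessels] = TissueClass.VESSEL

    # two correlated smooth lesion potentials, fixed per seed (not per day)
    sigma_vox = [1.2 / s for s in grid.spacing]
    inflam = ndimage.gaussian_filter(
        field_rng.standard_normal(grid.shape), sigma=sigma_vox
    )
    aux = ndimage.gaussian_filter(
        field_rng.standard_normal(grid.shape), sigma=sigma_vox
    )
    fibro = 0.6 * inflam + 0.8 * aux  # fibrosis clusters near inflammation

    voxvol = grid.voxel_volume
    n_edema = int(round(edema_mm3 / voxvol))
    n_tissue = int(round(tissue_mm3 / voxvol))
    n_lesion = n_edema + n_tissue
    eligible = lungs & ~vessels
    n_eligible = int(np.count_nonzero(eligible))
    if n_lesion > n_eligible:
        raise ValueError(
            f"lesion target volume {edema_mm3 + tissue_mm3:.0f} mm^3 exceeds the "
            f"available lung volume ({n_eligible * voxvol:.0f} mm^3)"
        )
    if n_lesion > 0:
        lab_flat = labels.ravel()
        elig_flat = eligible.ravel()
        if n_tissue > 0:
            flat_t = np.where(elig_flat, fibro.ravel(), -np.inf)
            core = np.argpartition(flat_t, -n_tissue)[-n_tissue:]
            lab_flat[core] = TissueClass.FIBROTIC_TISSUE
            elig_flat = elig_flat.copy()
            elig_flat[core] = False
        if n_edema > 0:
            flat_e = np.where(elig_flat, inflam.ravel(), -np.inf)
            ed = np.argpartition(flat_e, -n_edema)[-n_edema:]
            lab_flat[ed] = TissueClass.EDEMA
        labels = lab_flat.reshape(grid.shape)

        lesion = np.isin(labels, LESION_CLASSES)
        shell = ndimage.binary_dilation(lesion, structure=_SIX_CONN) & ~lesion
        labels[shell & (labels == TissueClass.LUNG_PARENCHYMA)] = TissueClass.ACTIVE_BORDER

    return TissueLabelMap(grid=grid, labels=labels)


# --------------------------------------------------------------------------
# signal simulation


def _check_labels(labels: np.ndarray) -> None:
    known = np.array([int(c) for c in TissueClass])
    bad = np.setdiff1d(np.unique(labels), known)
    if bad.size:
        raise ValueError(f"unknown class ids in label map: {bad.tolist()}")


def simulate_echo(
    label_map: TissueLabelMap,
    props: TissueProperties,
    te_ms: float,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate one UTE echo: mono-exponential T2* decay plus Rician noise.

    The noise-free voxel signal is ``PD(class) * exp(-TE / T2*(class))``.
    Magnitude noise is applied as the modulus of the complex signal with
    independent Gaussian perturbations of scale ``noise_sigma`` on both
    quadratures (Rician); with ``noise_sigma == 0`` the exact exponential
    model is returned.
    """
    if te_ms <= 0:
        raise ValueError("te_ms must be positive")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    _check_labels(label_map.labels)
    pd_lut = props.lut(props.proton_density)
    t2_lut = props.lut(props.t2_star)
    signal = pd_lut[label_map.labels] * np.exp(-te_ms / t2_lut[label_map.labels])
    if noise_sigma == 0:
        return signal
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 29]))
    re = signal + rng.normal(0.0, noise_sigma, signal.shape)
    im = rng.normal(0.0, noise_sigma, signal.shape)
    return np.hypot(re, im)


def simulate_echo_pair(
    label_map: TissueLabelMap,
    props: TissueProperties,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> EchoPair:
    """Simulate the co-registered short/long echo pair (distinct noise draws)."""
    return EchoPair(
        grid=label_map.grid,
        te_short_image=simulate_echo(label_map, props, TE_SHORT_MS, noise_sigma, seed * 2 + 1),
        te_long_image=simulate_echo(label_map, props, TE_LONG_MS, noise_sigma, seed * 2 + 2),
    )


def simulate_pet(
    label_map: TissueLabelMap,
    props: TissueProperties,
    pet_grid: GridSpec,
    psf_fwhm_mm: float = 0.8,
    injected_dose_mbq: float = 35.0,
    count_scale: float = np.inf,
    seed: int = 0,
    lung_fraction: float = 0.005,
    activity_scale: float | None = None,
    border_uptake_scale: float = 1.0,
    delay_minutes: float = 60.0,
    half_life_hours: float = CU64_HALF_LIFE_HOURS,
) -> PetVolume:
    """Simulate the static PET frame from the phantom label map.

    Relative per-class activity densities (``props.pet_uptake_density``, the
    active border scaled by ``border_uptake_scale``) are converted to absolute
    activity via ``activity_scale`` (MBq per relative density unit per mm^3).
    When ``activity_scale`` is None it is calibrated on *this* phantom so the
    total lung-region activity equals ``lung_fraction * injected_dose_mbq``;
    passing a fixed scale (e.g. one calibrated on a healthy baseline) lets
    diseased phantoms accumulate more activity than controls.  The
    concentration is rebinned onto ``pet_grid`` with exact volume weighting,
    blurred with a Gaussian PSF of the stated FWHM, and Poisson-perturbed at
    ``count_scale`` expected counts per MBq per voxel (infinite for noiseless).
    """
    if psf_fwhm_mm < 0:
        raise ValueError("psf_fwhm_mm must be nonnegative")
    if count_scale <= 0:
        raise ValueError("count_scale must be positive")
    if injected_dose_mbq <= 0:
        raise ValueError("injected_dose_mbq must be positive")
    if not pet_grid.covers(label_map.grid):
        raise ValueError("pet_grid does not cover the label-map extent")
    _check_labels(label_map.labels)

    dens = props.lut(props.pet_uptake_density).copy()
    dens[int(TissueClass.ACTIVE_BORDER)] *= border_uptake_scale
    density = dens[label_map.labels]

    voxvol = label_map.grid.voxel_volume
    if activity_scale is None:
        lung_total_rel = float(density[lung_region_mask(label_map.labels)].sum()) * voxvol
        if lung_total_rel <= 0:
            raise ValueError("lung region has zero uptake density; cannot calibrate")
        activity_scale = lung_fraction * injected_dose_mbq / lung_total_rel

    conc_mbq_mm3 = density * activity_scale
    conc = resample_intensive(conc_mbq_mm3, label_map.grid, pet_grid)

    if psf_fwhm_mm > 0:
        sigma_vox = [psf_fwhm_mm / 2.354820045 / s for s in pet_grid.spacing]
        conc = ndimage.gaussian_filter(conc, sigma=sigma_vox)

    if np.isfinite(count_scale):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 31]))
        lam = conc * pet_grid.voxel_volume * count_scale
        conc = rng.poisson(lam).astype(np.float64) / (count_scale * pet_grid.voxel_volume)

    activity_bq_ml = conc * 1e9  # MBq/mm^3 -> Bq/mL
    return PetVolume(
        grid=pet_grid,
        activity_concentration=activity_bq_ml,
        injected_dose_mbq=injected_dose_mbq,
        delay_minutes=delay_minutes,
        half_life_hours=half_life_hours,
        meta={
            "activity_scale_mbq_per_unit": float(activity_scale),
            "psf_fwhm_mm": float(psf_fwhm_mm),
            "count_scale": None if np.isinf(count_scale) else float(count_scale),
            "seed": int(seed),
        },
    )


# --------------------------------------------------------------------------
# longitudinal series


@dataclass(frozen=True)
class DayRecord:
    day: int
    label_map: TissueLabelMap
    echoes: EchoPair
    pet: PetVolume


@dataclass(frozen=True)
class PhantomSeries:
    """One simulated animal: per-day volumes plus the ground-truth table."""

    records: tuple[DayRecord, ...]
    truth: pd.DataFrame
    seed: int


def sigma_for_snr(snr: float, props: TissueProperties | None = None) -> float:
    """Rician noise scale giving a stated SNR on the short-echo edema signal."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    props = props or TissueProperties()
    sig = props.proton_density[TissueClass.EDEMA] * np.exp(
        -TE_SHORT_MS / props.t2_star[TissueClass.EDEMA]
    )
    return sig / snr


def _child_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([int(seed), *key]).generate_state(1)[0] % (2**31))


def make_series(
    trajectory: TrajectorySpec,
    mri_grid: GridSpec,
    pet_grid: GridSpec,
    props: TissueProperties | None = None,
    noise_sigma: float = 0.0,
    psf_fwhm_mm: float = 0.8,
    count_scale: float = np.inf,
    lung_fraction: float = 0.005,
    seed: int = 0,
) -> PhantomSeries:
    """Simulate a full longitudinal imaging series for one animal.

    One co-registered (label map, echo pair, PET) triplet per trajectory day.
    The injected dose (35 +/- 5 MBq) and injection-to-scan delay (60 +/- 5 min)
    are drawn per session.  The PET activity scale is calibrated once on the
    day-0 (healthy) phantom so the baseline lung holds ``lung_fraction`` of
    the injected dose; later days inherit that scale, so lesion borders add
    activity on top of the healthy background.  The returned ground-truth
    table records true per-class volumes and true (noise-free, PSF-free)
    per-compartment %ID for every day.
    """
    props = props or TissueProperties()
    records: list[DayRecord] = []
    truth_rows: list[dict] = []

    dose_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 41]))
    activity_scale: float | None = None

    for day in trajectory.days:
        label_map = make_label_map(mri_grid, trajectory, day, seed)
        echoes = simulate_echo_pair(
            label_map, props, noise_sigma, _child_seed(seed, 2, day)
        )
        dose = float(dose_rng.uniform(30.0, 40.0))
        delay = float(dose_rng.uniform(55.0, 65.0))
        _, _, border_scale = trajectory.at(day)

        if activity_scale is None:
            # calibrate on the baseline anatomy so disease adds activity
            baseline = label_map if day == 0 else make_label_map(mri_grid, trajectory, 0, seed)
            dens = props.lut(props.pet_uptake_density)[baseline.labels]
            lung_total = float(dens[lung_region_mask(baseline.labels)].sum())
            activity_scale = lung_fraction * dose / (lung_total * mri_grid.voxel_volume)

        pet = simulate_pet(
            label_map,
            props,
            pet_grid,
            psf_fwhm_mm=psf_fwhm_mm,
            injected_dose_mbq=dose,
            count_scale=count_scale,
            seed=_child_seed(seed, 3, day),
            activity_scale=activity_scale,
            border_uptake_scale=border_scale,
            delay_minutes=delay,
        )
        records.append(DayRecord(day=day, label_map=label_map, echoes=echoes, pet=pet))

        voxvol = mri_grid.voxel_volume
        dens = props.lut(props.pet_uptake_density).copy()
        dens[int(TissueClass.ACTIVE_BORDER)] *= border_scale
        density = dens[label_map.labels]
        def _pid(mask: np.ndarray) -> float:
            return 100.0 * float(density[mask].sum()) * voxvol * activity_scale / dose

        lung = lung_region_mask(label_map.labels)
        lesion = np.isin(label_map.labels, LESION_CLASSES)
        truth_rows.append(
            {
                "day": day,
                "edema_volume_mm3": label_map.volume_mm3(TissueClass.EDEMA),
                "tissue_volume_mm3": label_map.volume_mm3(TissueClass.FIBROTIC_TISSUE),
                "border_volume_mm3": label_map.volume_mm3(TissueClass.ACTIVE_BORDER),
                "vessel_volume_mm3": label_map.volume_mm3(TissueClass.VESSEL),
                "lung_volume_ml": float(lung.sum()) * voxvol / 1000.0,
                "injected_dose_mbq": dose,
                "delay_minutes": delay,
                "true_lung_percent_id": _pid(lung),
                "true_lesion_percent_id": _pid(lesion),
                "true_border_percent_id": _pid(label_map.labels == TissueClass.ACTIVE_BORDER),
                "activity_scale": activity_scale,
            }
        )

    return PhantomSeries(
        records=tuple(records), truth=pd.DataFrame(truth_rows), seed=int(seed)
    )
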