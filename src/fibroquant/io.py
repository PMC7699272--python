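"""NIfTI / JSON / CSV readers and writers with explicit grid geometry."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import GridSpec
from .phantom import EchoPair, PetVolume, PhantomSeries, TissueLabelMap
from .ute import RoiSet

__all__ = [
    "write_nifti",
    "read_nifti",
    "write_json",
    "read_json",
    "write_roiset",
    "read_roiset",
    "write_echo_pair",
    "read_echo_pair",
    "write_pet",
    "read_pet",
    "save_series",
]


def write_nifti(volume: np.ndarray, grid: GridSpec, path: str | Path) -> Path:
    grid.check_array(volume, "volume")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(volume), grid.affine())
    nib.save(img, str(path))
    return path


def read_nifti(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
    origin = tuple(float(aff[i, 3] - 0.5 * spacing[i]) for i in range(3))
    data = np.asanyarray(img.dataobj)
    grid = GridSpec(shape=tuple(data.shape), spacing=spacing, origin=origin)
    return data, grid


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_roiset(rois: RoiSet, path: str | Path) -> Path:
    """Write the ROI set as one multi-label volume plus a JSON label sidecar.

    Overlapping masks are encoded in priority order (tissue > edema >
    lesion_long > lesion_short > vessels > lung), matching how the
    compartments nest; the sidecar records the label dictionary.
    """
    labels = np.zeros(rois.grid.shape, dtype=np.uint8)
    for name in ("lung", "vessels", "lesion_short", "lesion_long", "edema", "tissue"):
        labels[getattr(rois, name)] = RoiSet.LABELS[name]
    path = Path(path)
    write_nifti(labels, rois.grid, path)
    write_json({"labels": RoiSet.LABELS}, path.with_suffix("").with_suffix(".json"))
    return path


def read_roiset(path: str | Path) -> RoiSet:
    labels, grid = read_nifti(path)
    lab = RoiSet.LABELS
    lung = labels >= lab["lung"]
    vessels = labels == lab["vessels"]
    lesion_long = np.isin(labels, [lab["lesion_long"], lab["edema"]])
    lesion_short = np.isin(
        labels, [lab["lesion_short"], lab["lesion_long"], lab["edema"], lab["tissue"]]
    )
    return RoiSet(
        grid=grid,
        lung=lung,
        vessels=vessels,
        lesion_short=lesion_short,
        lesion_long=lesion_long,
        edema=labels == lab["edema"],
        tissue=labels == lab["tissue"],
    )


def write_echo_pair(echoes: EchoPair, stem: str | Path) -> tuple[Path, Path]:
    stem = Path(stem)
    p_short = write_nifti(echoes.te_short_image, echoes.grid, stem.parent / f"{stem.name}_te_short.nii.gz")
    p_long = write_nifti(echoes.te_long_image, echoes.grid, stem.parent / f"{stem.name}_te_long.nii.gz")
    write_json(
        {"te_short_ms": echoes.te_short_ms, "te_long_ms": echoes.te_long_ms},
        stem.parent / f"{stem.name}_echoes.json",
    )
    return p_short, p_long


def read_echo_pair(stem: str | Path) -> EchoPair:
    stem = Path(stem)
    short, grid = read_nifti(stem.parent / f"{stem.name}_te_short.nii.gz")
    long_, _ = read_nifti(stem.parent / f"{stem.name}_te_long.nii.gz")
    meta = read_json(stem.parent / f"{stem.name}_echoes.json")
    return EchoPair(grid=grid, te_short_image=short, te_long_image=long_,
                    te_short_ms=meta["te_short_ms"], te_long_ms=meta["te_long_ms"])


def write_pet(pet: PetVolume, stem: str | Path) -> Path:
    stem = Path(stem)
    path = write_nifti(pet.activity_concentration, pet.grid, stem.parent / f"{stem.name}_pet.nii.gz")
    write_json(
        {
            "injected_dose_mbq": pet.injected_dose_mbq,
            "delay_minutes": pet.delay_minutes,
            "half_life_hours": pet.half_life_hours,
            **pet.meta,
        },
        stem.parent / f"{stem.name}_pet.json",
    )
    return path


def read_pet(stem: str | Path) -> PetVolume:
    stem = Path(stem)
    conc, grid = read_nifti(stem.parent / f"{stem.name}_pet.nii.gz")
    meta = read_json(stem.parent / f"{stem.name}_pet.json")
    return PetVolume(
        grid=grid,
        activity_concentration=conc,
        injected_dose_mbq=meta["injected_dose_mbq"],
        delay_minutes=meta["delay_minutes"],
        half_life_hours=meta["half_life_hours"],
        meta={k: v for k, v in meta.items()
              if k not in ("injected_dose_mbq", "delay_minutes", "half_life_hours")},
    )


def save_series(series: PhantomSeries, outdir: str | Path) -> Path:
    """Write a phantom series: per-day NIfTI volumes plus the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in series.records:
        stem = outdir / f"day{rec.day:02d}"
        write_nifti(rec.label_map.labels, rec.label_map.grid,
                    outdir / f"day{rec.day:02d}_labels.nii.gz")
        write_echo_pair(rec.echoes, stem)
        write_pet(rec.pet, stem)
    series.truth.to_csv(outdir / "ground_truth.csv", index=False)
    write_json({"seed": series.seed}, outdir / "series.json")
    return outdir
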