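"""Pipeline configuration: one serialisable record drives a whole run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .ute import THRESHOLD_RULES

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Resolved parameters of a phantom-to-report pipeline run.

    Defaults are the desk-scale study conditions: a 96^3 MRI grid at 0.6 mm,
    a PET grid at 0.4 mm isotropic, an imaging SNR of 20, a PET PSF of
    0.8 mm FWHM and a healthy-lung dose fraction of 0.5 %ID.  The full
    58 mm / 192-matrix in-plane resolution is available by overriding
    ``mri_shape``/``mri_spacing``.
    """

    # phantom grids
    mri_shape: tuple[int, int, int] = (96, 96, 96)
    mri_spacing: tuple[float, float, float] = (0.6, 0.6, 0.6)
    pet_spacing: tuple[float, float, float] = (0.4, 0.4, 0.4)
    # trajectory (mm^3 targets per day; None -> module defaults)
    days: tuple[int, ...] = (0, 7, 14, 21, 28)
    edema_volume_curve: tuple[float, ...] | None = None
    tissue_volume_curve: tuple[float, ...] | None = None
    control: bool = False
    # signal simulation
    snr: float = 20.0
    psf_fwhm_mm: float = 0.8
    count_scale: float | None = 1e7  # expected counts per MBq; None = noiseless
    lung_fraction: float = 0.005
    # analysis
    threshold_rule: str = "mode_fraction"
    min_component_voxels: int = 5
    n_rings: int = 5
    ring_width_mm: float = 0.8
    transform_path: str | None = None
    reference_genes: tuple[str, str] = ("B2M", "RLP13a")
    stats_method: str = "anova_bonferroni"
    # bookkeeping
    seed: int = 0
    outdir: str = "fibroquant_run"
    save_volumes: bool = False

    def __post_init__(self) -> None:
        if self.threshold_rule not in THRESHOLD_RULES:
            raise ValueError(
                f"unknown threshold rule {self.threshold_rule!r}; "
                f"choose from {THRESHOLD_RULES}"
            )
        if self.stats_method not in ("anova_bonferroni", "mann_whitney"):
            raise ValueError(f"unknown stats method {self.stats_method!r}")
        if self.snr <= 0 or self.lung_fraction <= 0:
            raise ValueError("snr and lung_fraction must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key in ("mri_shape", "mri_spacing", "pet_spacing", "days",
                    "edema_volume_curve", "tissue_volume_curve", "reference_genes"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
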