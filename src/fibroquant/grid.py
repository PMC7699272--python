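"""Sampling grids and volume resampling.

All volumes in this package live on axis-aligned regular grids described by a
:class:`GridSpec`.  Voxel indices are 0-based; the world coordinate of the
*corner* of voxel ``(0, 0, 0)`` is ``origin`` and voxel ``i`` occupies the
half-open box ``[origin + i*spacing, origin + (i+1)*spacing)`` (mm).  The
NIfTI affine produced by :meth:`GridSpec.affine` maps voxel indices to the
voxel *centres*, following the usual convention of nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "resample_intensive", "occupancy_resample"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular axis-aligned 3-D sampling grid.

    Parameters
    ----------
    shape
        Number of voxels along each axis (positive integers).
    spacing
        Voxel edge length per axis in mm (all > 0).
    origin
        World coordinate (mm) of the corner of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("GridSpec is strictly 3-D")
        if any(int(n) <= 0 or int(n) != n for n in self.shape):
            raise ValueError(f"shape must be positive integers, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> tuple[tuple[float, float], ...]:
        """Per-axis world interval ``[origin, origin + n*spacing)`` covered."""
        return tuple(
            (o, o + n * s) for o, n, s in zip(self.origin, self.shape, self.spacing)
        )

    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (voxel centre) affine for NIfTI output."""
        aff = np.diag([*self.spacing, 1.0])
        aff[:3, 3] = np.asarray(self.origin) + 0.5 * np.asarray(self.spacing)
        return aff

    def centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis."""
        o, s = self.origin[axis], self.spacing[axis]
        return o + s * (np.arange(self.shape[axis]) + 0.5)

    def covers(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        """Whether this grid's extent contains ``other``'s extent."""
        return all(
            a0 <= b0 + tol and a1 >= b1 - tol
            for (a0, a1), (b0, b1) in zip(self.extent, other.extent)
        )

    def check_array(self, volume: np.ndarray, name: str = "volume") -> None:
        if tuple(volume.shape) != self.shape:
            raise ValueError(
                f"{name} shape {tuple(volume.shape)} does not match grid {self.shape}"
            )


def _overlap_matrix(src: GridSpec, tgt: GridSpec, axis: int) -> np.ndarray:
    """1-D interval-overlap matrix W (n_tgt x n_src), in mm of overlap."""
    s_edges = src.origin[axis] + src.spacing[axis] * np.arange(src.shape[axis] + 1)
    t_edges = tgt.origin[axis] + tgt.spacing[axis] * np.arange(tgt.shape[axis] + 1)
    lo = np.maximum(t_edges[:-1, None], s_edges[None, :-1])
    hi = np.minimum(t_edges[1:, None], s_edges[None, 1:])
    return np.clip(hi - lo, 0.0, None)


def resample_intensive(
    values: np.ndarray, src: GridSpec, tgt: GridSpec
) -> np.ndarray:
    """Exact volume-weighted rebinning of an intensive quantity between grids.

    Each target voxel receives the overlap-volume-weighted mean of the source
    voxels it intersects (zero outside the source extent).  Because both grids
    are axis-aligned the 3-D box overlap factorises into three 1-D interval
    overlaps, applied as successive tensor contractions.  When the target
    extent covers the source extent the integral ``sum(values) * voxel_volume``
    is conserved to floating-point precision, which is what makes activity-
    concentration resampling suitable for percent-injected-dose accounting.
    """
    src.check_array(values, "values")
    out = values.astype(np.float64, copy=False)
    for axis in range(3):
        w = _overlap_matrix(src, tgt, axis)
        out = np.moveaxis(np.tensordot(w, np.moveaxis(out, axis, 0), axes=1), 0, axis)
    return out / tgt.voxel_volume


def occupancy_resample(
    mask: np.ndarray, src: GridSpec, tgt: GridSpec, threshold: float = 0.5
) -> np.ndarray:
    """Resample a boolean mask by fractional occupancy.

    A target voxel is set when the fraction of its volume covered by source
    mask voxels is >= ``threshold``.  Built on :func:`resample_intensive`
    applied to the 0/1 indicator, so the occupancy fractions are exact for
    axis-aligned grids.
    """
    frac = resample_intensive(mask.astype(np.float64), src, tgt)
    return frac >= threshold
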