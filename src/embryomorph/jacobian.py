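"""Jacobian-determinant fields for tensor-based morphometry.

The determinant of the spatial gradient of ``x -> x + u(x)`` measures the
local volume change a specimen undergoes during spatial normalisation:
``det(J) > 1`` means the specimen is locally larger than the population
average at that voxel, ``det(J) < 1`` locally smaller, and ``det(J) <= 0``
flags a folded (non-invertible) deformation. For morphometry only the
deformable (B-spline) stages contribute, so global pose and scale do not
masquerade as local volume change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageGrid, LabelMap, Volume, gaussian_smooth_fwhm
from .errors import DegenerateDataError, GridError
from .transforms import SpatialTransform, dense_displacement


@dataclass
class JacobianField:
    """det(J) values on the population-average grid plus provenance."""

    volume: Volume
    specimen_id: str = ""
    deformable_only: bool = True


def _gradient_determinants(u: np.ndarray, spacing_um: float) -> np.ndarray:
    """det(I + du/dx) via central finite differences (one-sided at borders)."""
    jac = np.empty((*u.shape[:3], 3, 3))
    for i in range(3):
        for j in range(3):
            jac[..., i, j] = np.gradient(u[..., i], spacing_um, axis=j)
        jac[..., i, i] += 1.0
    return np.linalg.det(jac)


def jacobian_determinant_field(
    transform: SpatialTransform,
    grid: ImageGrid,
    deformable_only: bool = True,
    specimen_id: str = "",
) -> JacobianField:
    """Jacobian determinant of a transform sampled on ``grid``.

    With ``deformable_only`` (the morphometry default), only B-spline stages
    of a composite transform contribute; a transform with zero deformable
    displacement therefore yields exactly 1.0 everywhere.
    """
    u = dense_displacement(transform, grid, deformable_only=deformable_only)
    if not np.any(u):
        dets = np.ones(grid.shape)
    else:
        dets = _gradient_determinants(u, grid.spacing_um)
    return JacobianField(Volume(grid, dets), specimen_id, deformable_only)


def smooth_and_mask(
    jf: JacobianField, mask: LabelMap, fwhm_um: float = 100.0
) -> Volume:
    """Smooth a determinant field (FWHM in μm) and blank voxels outside the
    mask with NaN so they are excluded from downstream statistics.

    Smoothing happens before masking, so boundary voxels see their full
    neighbourhood rather than the sentinel.
    """
    if mask.grid != jf.volume.grid:
        raise GridError("mask grid differs from Jacobian field grid")
    inside = mask.data > 0
    if not inside.any():
        raise DegenerateDataError("empty mask")
    smoothed = gaussian_smooth_fwhm(jf.volume, fwhm_um)
    out = smoothed.data.copy()
    out[~inside] = np.nan
    vol = Volume.__new__(Volume)  # bypass the finite-value check for the sentinel
    vol.grid = jf.volume.grid
    vol.data = out
    return vol


def negative_jacobian_report(jf: JacobianField) -> tuple[int, Volume]:
    """Count and binary map of voxels with ``det(J) <= 0`` (folding QC)."""
    neg = (jf.volume.data <= 0.0).astype(np.float64)
    return int(neg.sum()), Volume(jf.volume.grid, neg)


__all__ = [
    "JacobianField",
    "jacobian_determinant_field",
    "smooth_and_mask",
    "negative_jacobian_report",
]
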