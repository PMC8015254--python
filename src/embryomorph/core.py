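"""Image containers and shared numeric services.

Conventions used throughout the package:

* arrays are indexed ``(z, y, x)`` with 0-based voxel indices;
* world coordinates are micrometres, stored as ``(z, y, x)`` triples;
* the world coordinate of voxel ``i`` along an axis is
  ``origin_um + i * spacing_um`` (voxel-centre convention);
* spacing is isotropic — anisotropic grids are rejected at construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateDataError,
    GridError,
    MissingLabelError,
    ParameterError,
)

#: conversion between a Gaussian FWHM and its standard deviation
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class ImageGrid:
    """Geometry of a 3D image: shape (voxels), isotropic spacing and origin (μm)."""

    shape: tuple[int, int, int]
    spacing_um: float = 1.0
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise GridError(f"shape must be 3 positive integers, got {self.shape}")
        if not np.isfinite(self.spacing_um) or self.spacing_um <= 0:
            raise GridError(f"spacing_um must be positive, got {self.spacing_um}")
        origin = tuple(float(o) for o in self.origin_um)
        if len(origin) != 3 or not all(np.isfinite(origin)):
            raise GridError(f"origin_um must be 3 finite scalars, got {self.origin_um}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_um", float(self.spacing_um))
        object.__setattr__(self, "origin_um", origin)

    # -- geometry helpers -------------------------------------------------
    @property
    def extent_um(self) -> np.ndarray:
        """Physical size of the grid along each axis (μm)."""
        return (np.asarray(self.shape) - 1) * self.spacing_um

    @property
    def centre_um(self) -> np.ndarray:
        return np.asarray(self.origin_um) + self.extent_um / 2.0

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.spacing_um**3) * 1e-9

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin_um) + idx * self.spacing_um

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin_um)) / self.spacing_um

    def voxel_centres(self) -> np.ndarray:
        """World coordinates of all voxel centres, shape ``(*shape, 3)``."""
        axes = [
            self.origin_um[d] + np.arange(self.shape[d]) * self.spacing_um
            for d in range(3)
        ]
        zz, yy, xx = np.meshgrid(*axes, indexing="ij")
        return np.stack([zz, yy, xx], axis=-1)


@dataclass
class Volume:
    """A scalar 3D image on an :class:`ImageGrid`."""

    grid: ImageGrid
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise GridError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        if not np.all(np.isfinite(self.data)):
            raise DegenerateDataError("volume contains non-finite values")

    def copy(self) -> "Volume":
        return Volume(self.grid, self.data.copy())


@dataclass
class LabelMap:
    """Integer label image; 0 is reserved for background."""

    grid: ImageGrid
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise GridError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise GridError("label data must be integer valued")
            self.data = np.round(self.data).astype(np.int32)
        if self.data.min() < 0:
            raise GridError("labels must be non-negative")

    def labels(self) -> np.ndarray:
        """Sorted array of non-background labels present in the map."""
        u = np.unique(self.data)
        return u[u > 0]

    def copy(self) -> "LabelMap":
        return LabelMap(self.grid, self.data.copy())


@dataclass(frozen=True)
class LabelInfo:
    """Atlas metadata for one label."""

    label_id: int
    name: str
    ontology_id: str = ""
    is_thin: bool = False
    is_whole_embryo: bool = False

    def __post_init__(self):
        if self.label_id <= 0:
            raise ParameterError(f"label_id must be positive, got {self.label_id}")


def validate_label_info(infos: list[LabelInfo]) -> None:
    ids = [i.label_id for i in infos]
    if len(set(ids)) != len(ids):
        raise ParameterError("duplicate label ids in atlas metadata")
    if sum(i.is_whole_embryo for i in infos) > 1:
        raise ParameterError("at most one label may be flagged is_whole_embryo")


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

_INTERP_ORDER = {"trilinear": 1, "nearest": 0}


def _resample_array(
    data: np.ndarray,
    src_grid: ImageGrid,
    transform,
    out_grid: ImageGrid,
    order: int,
    cval: float,
) -> np.ndarray:
    pts = out_grid.voxel_centres().reshape(-1, 3)
    if transform is not None:
        pts = transform.apply(pts)
    idx = src_grid.world_to_index(pts)
    coords = idx.T.reshape(3, *out_grid.shape)
    return ndimage.map_coordinates(
        data, coords, order=order, mode="constant", cval=cval
    )


def resample_volume(
    vol: Volume,
    transform,
    out_grid: ImageGrid,
    interp: str = "trilinear",
    padding: float = 0.0,
) -> Volume:
    """Resample ``vol`` onto ``out_grid`` through a fixed→moving transform.

    The output value at an out-grid voxel ``x`` is ``vol`` interpolated at
    ``transform(x)``; ``transform=None`` means identity. Points mapping
    outside ``vol`` take the ``padding`` value.
    """
    if interp not in _INTERP_ORDER:
        raise ParameterError(f"interp must be one of {sorted(_INTERP_ORDER)}")
    out = _resample_array(
        vol.data.astype(np.float64),
        vol.grid,
        transform,
        out_grid,
        _INTERP_ORDER[interp],
        padding,
    )
    return Volume(out_grid, out)


def resample_labels(labels: LabelMap, transform, out_grid: ImageGrid) -> LabelMap:
    """Nearest-neighbour label resampling; background (0) outside the source."""
    out = _resample_array(
        labels.data, labels.grid, transform, out_grid, order=0, cval=0
    )
    return LabelMap(out_grid, out.astype(labels.data.dtype))


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


def gaussian_smooth_fwhm(vol: Volume, fwhm_um: float) -> Volume:
    """Gaussian smoothing parameterised by full-width-half-maximum in μm.

    ``sigma_um = fwhm_um / (2 sqrt(2 ln 2))``, converted to voxels via the
    grid spacing. Boundary mode is ``reflect`` so constant volumes are fixed
    points and mass is conserved.
    """
    if not np.isfinite(fwhm_um) or fwhm_um <= 0:
        raise ParameterError(f"fwhm_um must be positive, got {fwhm_um}")
    sigma_vox = fwhm_um * FWHM_TO_SIGMA / vol.grid.spacing_um
    out = ndimage.gaussian_filter(vol.data, sigma=sigma_vox, mode="reflect")
    return Volume(vol.grid, out)


# ---------------------------------------------------------------------------
# per-label distance transforms / thin-label flagging
# ---------------------------------------------------------------------------


def label_max_edt(labels: LabelMap, label_id: int) -> float:
    """Maximum Euclidean distance (voxel units) from a label to its exterior.

    The exterior is every non-label voxel; the domain is padded with one
    layer of background so the image border counts as exterior.
    """
    mask = labels.data == int(label_id)
    if not mask.any():
        raise MissingLabelError(f"label {label_id} not present")
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_edt(padded)
    return float(dist[1:-1, 1:-1, 1:-1][mask].max())


def flag_thin_labels(labels: LabelMap, cutoff: float = 1.5) -> set[int]:
    """Labels whose maximum interior EDT is strictly below ``cutoff`` (voxels).

    These are the small/spindly structures excluded from downstream
    statistics; the comparison is strict, so a label sitting exactly at the
    cutoff is retained.
    """
    return {
        int(lab)
        for lab in labels.labels()
        if label_max_edt(labels, int(lab)) < cutoff
    }


# ---------------------------------------------------------------------------
# intensity normalisation
# ---------------------------------------------------------------------------


def normalize_intensity(vol: Volume, mask: LabelMap | None = None) -> Volume:
    """Standardise intensities to mean 0 / sd 1 within ``mask`` (or globally).

    Affine intensity changes of the input yield identical output, which makes
    specimens with different intensity profiles comparable before averaging.
    """
    if mask is not None:
        if mask.grid != vol.grid:
            raise GridError("mask grid differs from volume grid")
        vals = vol.data[mask.data > 0]
        if vals.size == 0:
            raise DegenerateDataError("empty mask")
    else:
        vals = vol.data.reshape(-1)
    mu = float(vals.mean())
    sd = float(vals.std())
    if sd == 0.0 or sd < 1e-12 * max(1.0, abs(mu)):
        raise DegenerateDataError("zero intensity variance within mask")
    return Volume(vol.grid, (vol.data - mu) / sd)


def foreground_mask(vol: Volume, frac: float = 0.05, dilate: int = 2) -> LabelMap:
    """Crude foreground mask: voxels above ``frac`` of the intensity range,
    dilated to include the object boundary. Falls back to the full volume
    when the threshold captures (almost) nothing."""
    lo, hi = float(vol.data.min()), float(vol.data.max())
    mask = vol.data > lo + frac * (hi - lo)
    if dilate > 0 and mask.any():
        mask = ndimage.binary_dilation(mask, iterations=dilate)
    if mask.sum() < 0.01 * mask.size:
        mask = np.ones(vol.grid.shape, dtype=bool)
    return LabelMap(vol.grid, mask.astype(np.int32))


__all__ = [
    "FWHM_TO_SIGMA",
    "ImageGrid",
    "Volume",
    "LabelMap",
    "LabelInfo",
    "validate_label_info",
    "resample_volume",
    "resample_labels",
    "gaussian_smooth_fwhm",
    "label_max_edt",
    "flag_thin_labels",
    "normalize_intensity",
    "foreground_mask",
]
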