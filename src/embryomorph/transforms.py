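"""Spatial transforms: rigid/similarity/affine, cubic B-spline free-form
deformations, dense displacement fields and their composition/inversion.

All transforms map *fixed-space* world points (μm, ``(z, y, x)`` order) to
*moving-space* world points. Warping a moving image onto the fixed grid uses
the transform directly; propagating fixed-space labels into moving space uses
its inverse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import ImageGrid
from .errors import FoldError, InversionError, ParameterError

# ---------------------------------------------------------------------------
# base / linear transforms
# ---------------------------------------------------------------------------


class SpatialTransform:
    """Interface: ``apply`` maps ``(..., 3)`` world points to world points."""

    def apply(self, points: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def to_dict(self) -> dict:  # pragma: no cover
        raise NotImplementedError


@dataclass
class IdentityTransform(SpatialTransform):
    def apply(self, points):
        return np.asarray(points, dtype=float)

    def to_dict(self):
        return {"type": "identity"}


@dataclass
class AffineTransform(SpatialTransform):
    """``T(x) = A (x - c) + c + t`` with invertible 3×3 ``A``."""

    matrix: np.ndarray
    translation: np.ndarray
    centre: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.centre = np.asarray(self.centre, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ParameterError("affine matrix is singular")

    def apply(self, points):
        pts = np.asarray(points, dtype=float)
        return (pts - self.centre) @ self.matrix.T + self.centre + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation, self.centre)

    def to_dict(self):
        return {
            "type": "affine",
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
            "centre": self.centre.tolist(),
        }


def rotation_matrix_zyx(angles: np.ndarray) -> np.ndarray:
    """Rotation matrix in the ``(z, y, x)`` basis from three angles (radians).

    ``angles = (a, b, c)`` rotate successively about the z, y and x world
    axes; the result is ``Rz(a) @ Ry(b) @ Rx(c)``.
    """
    a, b, c = [float(v) for v in np.asarray(angles).reshape(3)]
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    # rotation about z mixes (y, x); about y mixes (z, x); about x mixes (z, y)
    rz = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]], dtype=float)
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]], dtype=float)
    rx = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]], dtype=float)
    return rz @ ry @ rx


@dataclass
class RigidTransform(AffineTransform):
    """Rotation + translation about a world-space centre."""

    def __init__(self, angles, translation, centre):
        self.angles = np.asarray(angles, dtype=float).reshape(3)
        super().__init__(rotation_matrix_zyx(self.angles), translation, centre)

    def to_dict(self):
        d = super().to_dict()
        d.update(type="rigid", angles=self.angles.tolist())
        return d


@dataclass
class SimilarityTransform(AffineTransform):
    """Isotropic scale × rotation + translation about a centre."""

    def __init__(self, angles, scale, translation, centre):
        if scale <= 0:
            raise ParameterError("similarity scale must be positive")
        self.angles = np.asarray(angles, dtype=float).reshape(3)
        self.scale = float(scale)
        super().__init__(
            self.scale * rotation_matrix_zyx(self.angles), translation, centre
        )

    def to_dict(self):
        d = super().to_dict()
        d.update(type="similarity", angles=self.angles.tolist(), scale=self.scale)
        return d


def translation_transform(t) -> AffineTransform:
    return AffineTransform(np.eye(3), t, np.zeros(3))


# ---------------------------------------------------------------------------
# B-spline free-form deformation
# ---------------------------------------------------------------------------


@dataclass
class BSplineFFD(SpatialTransform):
    """Cubic B-spline FFD: displacements interpolated from a control lattice.

    ``coeffs`` holds the control-point displacement vectors (μm) on a regular
    lattice with world origin ``origin_um`` and spacing ``spacing_um``; the
    displacement at a point is the tensor-product cubic B-spline interpolant.
    """

    origin_um: np.ndarray
    spacing_um: float
    coeffs: np.ndarray
    control_spacing_vox: float | None = None  # provenance: spacing in fixed voxels

    def __post_init__(self):
        self.origin_um = np.asarray(self.origin_um, dtype=float).reshape(3)
        self.spacing_um = float(self.spacing_um)
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 4 or self.coeffs.shape[-1] != 3:
            raise ParameterError("coeffs must have shape (nz, ny, nx, 3)")
        if self.spacing_um <= 0:
            raise ParameterError("control spacing must be positive")

    @classmethod
    def for_image_grid(
        cls, grid: ImageGrid, control_spacing_vox: float
    ) -> "BSplineFFD":
        """Zero-displacement FFD covering ``grid`` plus the cubic support margin."""
        h = control_spacing_vox * grid.spacing_um
        origin = np.asarray(grid.origin_um) - h
        n = np.ceil(grid.extent_um / h).astype(int) + 4
        return cls(origin, h, np.zeros((*n, 3)), float(control_spacing_vox))

    def control_coords(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin_um) / self.spacing_um

    def displacement(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        flat = pts.reshape(-1, 3)
        cc = self.control_coords(flat).T  # (3, N)
        u = np.empty_like(flat)
        for d in range(3):
            # coeffs ARE the spline coefficients: no prefilter
            u[:, d] = ndimage.map_coordinates(
                self.coeffs[..., d], cc, order=3, prefilter=False, mode="constant"
            )
        return u.reshape(pts.shape)

    def apply(self, points):
        pts = np.asarray(points, dtype=float)
        return pts + self.displacement(pts)

    def to_dict(self):
        return {
            "type": "bspline",
            "origin_um": self.origin_um.tolist(),
            "spacing_um": self.spacing_um,
            "control_spacing_vox": self.control_spacing_vox,
            "coeffs": self.coeffs.tolist(),
        }


@dataclass
class DenseFieldTransform(SpatialTransform):
    """Displacement field sampled on a grid, interpolated trilinearly."""

    grid: ImageGrid
    field_um: np.ndarray  # (*grid.shape, 3)

    def __post_init__(self):
        self.field_um = np.asarray(self.field_um, dtype=float)
        if self.field_um.shape != (*self.grid.shape, 3):
            raise ParameterError("field shape must be (*grid.shape, 3)")

    def displacement(self, points):
        pts = np.asarray(points, dtype=float)
        idx = self.grid.world_to_index(pts.reshape(-1, 3)).T
        u = np.empty((idx.shape[1], 3))
        for d in range(3):
            u[:, d] = ndimage.map_coordinates(
                self.field_um[..., d], idx, order=1, mode="nearest"
            )
        return u.reshape(pts.shape)

    def apply(self, points):
        pts = np.asarray(points, dtype=float)
        return pts + self.displacement(pts)

    def to_dict(self):
        return {
            "type": "dense",
            "grid": {
                "shape": list(self.grid.shape),
                "spacing_um": self.grid.spacing_um,
                "origin_um": list(self.grid.origin_um),
            },
            "field_um": self.field_um.tolist(),
        }


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

STAGE_TAGS = ("rigid", "similarity", "affine", "deformable")


@dataclass
class CompositeTransform(SpatialTransform):
    """Ordered registration stages.

    ``stages`` is kept in the order the stages were fitted; evaluation
    applies the most recently fitted stage first (innermost), i.e. for
    stages ``[s1, s2, ..., sk]``, ``T(x) = s1(s2(... sk(x)))``.
    """

    stages: list[tuple[str, SpatialTransform]] = field(default_factory=list)

    def __post_init__(self):
        for tag, _ in self.stages:
            if tag not in STAGE_TAGS:
                raise ParameterError(f"unknown stage tag {tag!r}")

    def apply(self, points):
        pts = np.asarray(points, dtype=float)
        for _, t in reversed(self.stages):
            pts = t.apply(pts)
        return pts

    def append(self, tag: str, transform: SpatialTransform) -> None:
        if tag not in STAGE_TAGS:
            raise ParameterError(f"unknown stage tag {tag!r}")
        self.stages.append((tag, transform))

    def deformable_only(self) -> "CompositeTransform":
        """Sub-composition of the B-spline (deformable) stages only."""
        return CompositeTransform(
            [(tag, t) for tag, t in self.stages if tag == "deformable"]
        )

    def to_dict(self):
        return {
            "type": "composite",
            "stages": [{"tag": tag, "transform": t.to_dict()} for tag, t in self.stages],
        }


def dense_displacement(
    transform: SpatialTransform, grid: ImageGrid, deformable_only: bool = False
) -> np.ndarray:
    """Displacement ``u(x) = T(x) - x`` (μm) at voxel centres, ``(*shape, 3)``.

    With ``deformable_only`` and a composite transform, only the B-spline
    stages contribute — the field used for Jacobian-determinant morphometry,
    where rigid/affine pose and scale must not register as volume change.
    """
    if deformable_only and isinstance(transform, CompositeTransform):
        transform = transform.deformable_only()
    elif deformable_only and not isinstance(
        transform, (BSplineFFD, DenseFieldTransform)
    ):
        return np.zeros((*grid.shape, 3))
    pts = grid.voxel_centres()
    return transform.apply(pts) - pts


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------


def _invert_deformable(
    stage: SpatialTransform, grid: ImageGrid, tol_um: float, max_iter: int
) -> DenseFieldTransform:
    """Fixed-point inversion of a displacement transform on ``grid``:
    iterate ``v <- -u(x + v)`` until the update stalls."""
    pts = grid.voxel_centres()
    v = np.zeros_like(pts)
    for _ in range(max_iter):
        v_new = -stage.displacement(pts + v)
        delta = float(np.abs(v_new - v).max())
        v = v_new
        if delta < 0.1 * tol_um:
            break
    return DenseFieldTransform(grid, v)


def invert_transform(
    transform: SpatialTransform,
    grid: ImageGrid,
    tol_um: float | None = None,
    max_iter: int = 50,
    probe_stride: int = 4,
) -> SpatialTransform:
    """Invert a transform; linear stages in closed form, deformable stages by
    fixed-point iteration of the displacement field on ``grid``.

    Raises :class:`FoldError` when the transform has non-positive Jacobian
    determinants in the domain and :class:`InversionError` when the
    round-trip residual ``max ||T(T⁻¹(x)) - x||`` on a probe grid exceeds
    ``tol_um`` (default: a quarter voxel).
    """
    if tol_um is None:
        tol_um = 0.25 * grid.spacing_um

    from .jacobian import jacobian_determinant_field  # cycle-free at call time

    dets = jacobian_determinant_field(transform, grid, deformable_only=False)
    if float(dets.volume.data.min()) <= 0.0:
        raise FoldError(
            "transform folds (non-positive Jacobian determinant) in the domain"
        )

    def invert_stage(tag, t):
        if isinstance(t, AffineTransform):
            return t.inverse()
        if isinstance(t, (BSplineFFD, DenseFieldTransform)):
            return _invert_deformable(t, grid, tol_um, max_iter)
        if isinstance(t, IdentityTransform):
            return t
        raise InversionError(f"cannot invert stage type {type(t).__name__}")

    if isinstance(transform, CompositeTransform):
        inv = CompositeTransform(
            [(tag, invert_stage(tag, t)) for tag, t in reversed(transform.stages)]
        )
    else:
        inv = invert_stage("deformable", transform)

    probe = grid.voxel_centres()[::probe_stride, ::probe_stride, ::probe_stride]
    probe = probe.reshape(-1, 3)
    residual = np.linalg.norm(
        transform.apply(inv.apply(probe)) - probe, axis=-1
    )
    worst = float(residual.max())
    if worst > tol_um:
        raise InversionError(
            f"round-trip residual {worst:.3g} μm exceeds tolerance {tol_um:.3g} μm",
            worst_residual_um=worst,
        )
    inv.round_trip_residual_um = worst  # type: ignore[attr-defined]
    return inv


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------


def transform_from_dict(d: dict) -> SpatialTransform:
    t = d["type"]
    if t == "identity":
        return IdentityTransform()
    if t == "rigid":
        return RigidTransform(d["angles"], d["translation"], d["centre"])
    if t == "similarity":
        return SimilarityTransform(d["angles"], d["scale"], d["translation"], d["centre"])
    if t == "affine":
        return AffineTransform(d["matrix"], d["translation"], d["centre"])
    if t == "bspline":
        return BSplineFFD(
            d["origin_um"], d["spacing_um"], np.asarray(d["coeffs"]),
            d.get("control_spacing_vox"),
        )
    if t == "dense":
        g = d["grid"]
        return DenseFieldTransform(
            ImageGrid(tuple(g["shape"]), g["spacing_um"], tuple(g["origin_um"])),
            np.asarray(d["field_um"]),
        )
    if t == "composite":
        return CompositeTransform(
            [(s["tag"], transform_from_dict(s["transform"])) for s in d["stages"]]
        )
    raise ParameterError(f"unknown transform type {t!r}")


def save_transform(path: str | Path, transform: SpatialTransform) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(transform.to_dict()))


def load_transform(path: str | Path) -> SpatialTransform:
    return transform_from_dict(json.loads(Path(path).read_text()))


__all__ = [
    "SpatialTransform",
    "IdentityTransform",
    "AffineTransform",
    "RigidTransform",
    "SimilarityTransform",
    "BSplineFFD",
    "DenseFieldTransform",
    "CompositeTransform",
    "translation_transform",
    "rotation_matrix_zyx",
    "dense_displacement",
    "invert_transform",
    "transform_from_dict",
    "save_transform",
    "load_transform",
]
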