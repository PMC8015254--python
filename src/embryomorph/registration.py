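"""Pairwise multi-resolution registration: rigid → similarity → affine →
multi-level cubic B-spline free-form deformation.

The similarity metric is normalised cross-correlation (NCC) over the fixed
image's foreground, which is invariant to affine intensity rescaling of
either image — important when specimens have different intensity profiles.
Each stage is optimised with regular-step gradient ascent (step halving on
metric worsening), using analytic NCC derivatives chained through sampled
moving-image gradients; B-spline stages scatter the per-voxel force field
onto the control lattice with separable cubic-kernel correlations. The
optimisation is deterministic: no stochastic sampling is used, and the
``seed`` argument exists so that any future subset sampling stays keyed to
the run seed.

The fitted :class:`~embryomorph.transforms.CompositeTransform` maps fixed
world points to moving world points, so warping the moving image onto the
fixed grid uses it directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ImageGrid, LabelMap, Volume, foreground_mask, resample_volume
from .errors import DegenerateDataError, ParameterError, RegistrationError
from .transforms import (
    AffineTransform,
    BSplineFFD,
    CompositeTransform,
    RigidTransform,
    SimilarityTransform,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PyramidLevel:
    """One resolution level: integer downsampling factor + Gaussian smoothing
    (sigma in voxels of the full-resolution image) applied before subsampling."""

    factor: int = 1
    smooth_sigma_vox: float = 0.0

    def __post_init__(self):
        if self.factor < 1:
            raise ParameterError("pyramid factor must be >= 1")


@dataclass(frozen=True)
class LinearStageSpec:
    kind: str  # rigid | similarity | affine
    levels: tuple[PyramidLevel, ...]
    iterations: int = 200
    initial_step_vox: float = 2.0
    min_step_frac: float = 1e-3

    def __post_init__(self):
        if self.kind not in ("rigid", "similarity", "affine"):
            raise ParameterError(f"unknown linear stage kind {self.kind!r}")
        _check_coarse_to_fine(self.levels)


@dataclass(frozen=True)
class DeformableStageSpec:
    control_spacing_vox: float = 8.0
    level: PyramidLevel = PyramidLevel()
    iterations: int = 300
    initial_step_vox: float = 1.0
    min_step_frac: float = 1e-3
    bending_weight: float = 0.0

    kind: str = field(default="deformable", init=False)


def _check_coarse_to_fine(levels):
    if not levels:
        raise ParameterError("stage needs at least one pyramid level")
    factors = [l.factor for l in levels]
    if any(b > a for a, b in zip(factors, factors[1:])):
        raise ParameterError("pyramid must run coarse → fine")


@dataclass(frozen=True)
class RegistrationSchedule:
    stages: tuple

    def __post_init__(self):
        spacings = [
            s.control_spacing_vox
            for s in self.stages
            if isinstance(s, DeformableStageSpec)
        ]
        if any(b >= a for a, b in zip(spacings, spacings[1:])):
            raise ParameterError("B-spline control spacings must strictly decrease")
        deform_factors = [
            s.level.factor for s in self.stages if isinstance(s, DeformableStageSpec)
        ]
        if any(b > a for a, b in zip(deform_factors, deform_factors[1:])):
            raise ParameterError("deformable pyramid must run coarse → fine")

    @property
    def finest_control_spacing_vox(self) -> float | None:
        spacings = [
            s.control_spacing_vox
            for s in self.stages
            if isinstance(s, DeformableStageSpec)
        ]
        return spacings[-1] if spacings else None

    def linear_only(self) -> "RegistrationSchedule":
        return RegistrationSchedule(
            tuple(s for s in self.stages if isinstance(s, LinearStageSpec))
        )

    def prefix(self, n: int) -> "RegistrationSchedule":
        return RegistrationSchedule(self.stages[:n])


def default_schedule(
    include_similarity: bool = True,
    iterations_linear: int = 200,
    iterations_deformable: int = 300,
    bending_weight_finest: float = 0.01,
) -> RegistrationSchedule:
    """Default stage structure: rigid, similarity, affine (3-level pyramids,
    factors 4/2/1), then a five-level B-spline schedule with control
    spacings 64 → 32 → 16 → 12 → 8 voxels, ending at 8. The similarity stage
    can be switched off."""
    linear_levels = (
        PyramidLevel(4, 2.0),
        PyramidLevel(2, 1.0),
        PyramidLevel(1, 0.0),
    )
    stages: list = [LinearStageSpec("rigid", linear_levels, iterations_linear)]
    if include_similarity:
        stages.append(LinearStageSpec("similarity", linear_levels, iterations_linear))
    stages.append(LinearStageSpec("affine", linear_levels, iterations_linear))
    bspline_plan = [(64.0, 4, 2.0), (32.0, 4, 2.0), (16.0, 2, 1.0), (12.0, 2, 1.0), (8.0, 1, 0.0)]
    for i, (spacing, factor, sigma) in enumerate(bspline_plan):
        stages.append(
            DeformableStageSpec(
                control_spacing_vox=spacing,
                level=PyramidLevel(factor, sigma),
                iterations=iterations_deformable,
                bending_weight=bending_weight_finest if i == len(bspline_plan) - 1 else 0.0,
            )
        )
    return RegistrationSchedule(tuple(stages))


def compact_schedule(
    control_spacings=(16.0, 8.0),
    iterations_linear: int = 80,
    iterations_deformable: int = 80,
    include_similarity: bool = False,
) -> RegistrationSchedule:
    """Reduced schedule for small (≲64³) volumes: same stage structure,
    shorter pyramids and fewer iterations."""
    linear_levels = (PyramidLevel(4, 2.0), PyramidLevel(2, 1.0))
    stages: list = [LinearStageSpec("rigid", linear_levels, iterations_linear)]
    if include_similarity:
        stages.append(LinearStageSpec("similarity", linear_levels, iterations_linear))
    stages.append(LinearStageSpec("affine", linear_levels, iterations_linear))
    factors = [2] * (len(control_spacings) - 1) + [1]
    for spacing, factor in zip(control_spacings, factors):
        stages.append(
            DeformableStageSpec(
                control_spacing_vox=float(spacing),
                level=PyramidLevel(factor, 1.0 if factor > 1 else 0.0),
                iterations=iterations_deformable,
                bending_weight=0.01 if spacing == control_spacings[-1] else 0.0,
            )
        )
    return RegistrationSchedule(tuple(stages))


# ---------------------------------------------------------------------------
# metric
# ---------------------------------------------------------------------------


def ncc_metric(fixed: Volume, moving_resampled: Volume, mask: LabelMap | None = None):
    """Pearson correlation of intensities within the mask (or everywhere)."""
    if fixed.grid != moving_resampled.grid:
        raise ParameterError("fixed and moving must share a grid")
    if mask is not None:
        sel = mask.data > 0
        f = fixed.data[sel]
        m = moving_resampled.data[sel]
    else:
        f = fixed.data.reshape(-1)
        m = moving_resampled.data.reshape(-1)
    return _ncc(f - f.mean(), m)[0]


def _ncc(a_centred: np.ndarray, m: np.ndarray):
    """NCC between a pre-centred reference and ``m``; also returns the
    derivative of the NCC with respect to each ``m`` sample."""
    b = m - m.mean()
    saa = float(a_centred @ a_centred)
    sbb = float(b @ b)
    if saa <= 0 or sbb <= 0:
        raise DegenerateDataError("zero intensity variance within the metric mask")
    sab = float(a_centred @ b)
    denom = np.sqrt(saa * sbb)
    ncc = sab / denom
    dm = (a_centred - (sab / sbb) * b) / denom
    return ncc, dm


# ---------------------------------------------------------------------------
# trace
# ---------------------------------------------------------------------------


@dataclass
class MetricTrace:
    """Per-stage, per-level metric-versus-iteration record."""

    records: list[dict] = field(default_factory=list)

    def add(self, stage: str, stage_index: int, level: int, iteration: int, metric: float):
        self.records.append(
            {
                "stage": stage,
                "stage_index": stage_index,
                "level": level,
                "iteration": iteration,
                "metric": metric,
            }
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def final_metric(self) -> float:
        return self.records[-1]["metric"] if self.records else np.nan


# ---------------------------------------------------------------------------
# pyramids
# ---------------------------------------------------------------------------


def _downsample(vol: Volume, level: PyramidLevel) -> Volume:
    data = vol.data
    if level.smooth_sigma_vox > 0:
        data = ndimage.gaussian_filter(data, level.smooth_sigma_vox, mode="reflect")
    f = level.factor
    if f > 1:
        data = data[::f, ::f, ::f]
    grid = ImageGrid(data.shape, vol.grid.spacing_um * f, vol.grid.origin_um)
    return Volume(grid, data)


def _sample(data: np.ndarray, grid: ImageGrid, pts: np.ndarray) -> np.ndarray:
    idx = grid.world_to_index(pts).T
    return ndimage.map_coordinates(data, idx, order=1, mode="constant", cval=0.0)


# ---------------------------------------------------------------------------
# linear stages
# ---------------------------------------------------------------------------


def _linear_param_count(kind: str) -> int:
    return {"rigid": 6, "similarity": 7, "affine": 12}[kind]


def _linear_transform(kind: str, p: np.ndarray, centre: np.ndarray):
    if kind == "rigid":
        return RigidTransform(p[:3], p[3:6], centre)
    if kind == "similarity":
        return SimilarityTransform(p[:3], float(np.exp(p[3])), p[4:7], centre)
    return AffineTransform(np.eye(3) + p[:9].reshape(3, 3), p[9:12], centre)


def _linear_scales(kind: str, domain_radius_um: float) -> np.ndarray:
    r = domain_radius_um
    if kind == "rigid":
        return np.array([r, r, r, 1, 1, 1], dtype=float)
    if kind == "similarity":
        return np.array([r, r, r, r, 1, 1, 1], dtype=float)
    return np.array([r] * 9 + [1, 1, 1], dtype=float)


def _optimize_linear(
    stage: LinearStageSpec,
    fixed: Volume,
    moving: Volume,
    centre: np.ndarray,
    trace: MetricTrace,
    stage_index: int,
) -> AffineTransform:
    kind = stage.kind
    n_par = _linear_param_count(kind)
    radius = float(np.linalg.norm(fixed.grid.extent_um) / 2.0)
    scales = _linear_scales(kind, radius)
    q = np.zeros(n_par)  # scaled parameters; identity start

    for li, level in enumerate(stage.levels):
        fx = _downsample(fixed, level)
        mv = _downsample(moving, level)
        mask = foreground_mask(fx).data > 0
        pts = fx.grid.voxel_centres()[mask]
        f = fx.data[mask]
        fc = f - f.mean()
        grads = np.stack(np.gradient(mv.data, mv.grid.spacing_um), axis=-1)

        def value(qv):
            t = _linear_transform(kind, qv / scales, centre)
            return _ncc(fc, _sample(mv.data, mv.grid, t.apply(pts)))[0]

        def value_grad(qv):
            t = _linear_transform(kind, qv / scales, centre)
            mapped = t.apply(pts)
            m = _sample(mv.data, mv.grid, mapped)
            ncc, w = _ncc(fc, m)
            dm = np.stack(
                [_sample(grads[..., d], mv.grid, mapped) for d in range(3)], axis=-1
            )
            g = np.empty(n_par)
            eps = 1e-3
            for j in range(n_par):
                qp, qm = qv.copy(), qv.copy()
                qp[j] += eps
                qm[j] -= eps
                dT = (
                    _linear_transform(kind, qp / scales, centre).apply(pts)
                    - _linear_transform(kind, qm / scales, centre).apply(pts)
                ) / (2 * eps)
                g[j] = float(np.sum(w * np.einsum("ij,ij->i", dm, dT)))
            return ncc, g

        step0 = stage.initial_step_vox * fx.grid.spacing_um
        q = _ascend(
            q, value, value_grad, step0, stage.min_step_frac * step0,
            stage.iterations, trace, kind, stage_index, li,
        )
    return _linear_transform(kind, q / scales, centre)


def _ascend(
    q, value, value_grad, step0, min_step, iterations, trace, stage, stage_index, level
):
    """Regular-step gradient ascent with step halving on metric worsening."""
    metric = value(q)
    first = metric
    trace.add(stage, stage_index, level, 0, metric)
    step = step0
    for it in range(1, iterations + 1):
        m_here, g = value_grad(q)
        gnorm = float(np.linalg.norm(g))
        if gnorm == 0.0:
            break
        cand = q + step * g / gnorm
        m_cand = value(cand)
        if m_cand > metric + 1e-12:
            q, metric = cand, m_cand
        else:
            step *= 0.5
        trace.add(stage, stage_index, level, it, metric)
        if step < min_step:
            break
    if metric < first - 1e-6:
        raise RegistrationError(
            f"metric worsened over stage {stage} level {level}", trace
        )
    return q


# ---------------------------------------------------------------------------
# deformable stage
# ---------------------------------------------------------------------------


def _bspline3(t: np.ndarray) -> np.ndarray:
    at = np.abs(t)
    out = np.zeros_like(at)
    inner = at < 1
    outer = (at >= 1) & (at < 2)
    out[inner] = (4 - 6 * at[inner] ** 2 + 3 * at[inner] ** 3) / 6.0
    out[outer] = (2 - at[outer]) ** 3 / 6.0
    return out


def _optimize_deformable(
    stage: DeformableStageSpec,
    fixed: Volume,
    moving: Volume,
    trace: MetricTrace,
    stage_index: int,
) -> BSplineFFD:
    ffd = BSplineFFD.for_image_grid(fixed.grid, stage.control_spacing_vox)
    level = stage.level
    fx = _downsample(fixed, level)
    mv = _downsample(moving, level)
    mask = foreground_mask(fx).data > 0
    pts = fx.grid.voxel_centres()
    pts_m = pts[mask]
    f = fx.data[mask]
    fc = f - f.mean()
    grads = np.stack(np.gradient(mv.data, mv.grid.spacing_um), axis=-1)

    # control-lattice geometry in level-voxel units
    h = ffd.spacing_um
    su = fx.grid.spacing_um
    r = su / h
    cc_masked = ffd.control_coords(pts_m).T  # (3, Nmask)
    alpha = (np.asarray(fx.grid.origin_um) - ffd.origin_um) / h  # cc = alpha + i*r
    nctrl = ffd.coeffs.shape[:3]
    ctrl_idx = [
        (np.arange(nctrl[d]) - alpha[d]) / r for d in range(3)
    ]  # level-voxel position of each control point
    zz, yy, xx = np.meshgrid(*ctrl_idx, indexing="ij")
    ctrl_coords = np.stack([zz, yy, xx]).reshape(3, -1)
    L = int(np.floor(2.0 / r)) if r < 2 else 0
    kernel = _bspline3(np.arange(-L, L + 1) * r) if L > 0 else np.array([1.0])
    lam = stage.bending_weight

    def displacement(coeffs):
        u = np.empty((cc_masked.shape[1], 3))
        for d in range(3):
            u[:, d] = ndimage.map_coordinates(
                coeffs[..., d], cc_masked, order=3, prefilter=False, mode="constant"
            )
        return u

    def penalty(coeffs):
        if lam == 0.0:
            return 0.0, None
        lap = np.stack(
            [ndimage.laplace(coeffs[..., d], mode="constant") for d in range(3)],
            axis=-1,
        )
        val = float(np.mean(lap**2)) / max(h, 1.0) ** 2
        grad = np.stack(
            [ndimage.laplace(lap[..., d], mode="constant") for d in range(3)], axis=-1
        ) * (2.0 / (lap.size / 3) / max(h, 1.0) ** 2)
        return val, grad

    def value(coeffs):
        mapped = pts_m + displacement(coeffs)
        m = _sample(mv.data, mv.grid, mapped)
        pen, _ = penalty(coeffs)
        return _ncc(fc, m)[0] - lam * pen

    def value_grad(coeffs):
        mapped = pts_m + displacement(coeffs)
        m = _sample(mv.data, mv.grid, mapped)
        ncc, w = _ncc(fc, m)
        grad = np.zeros_like(coeffs)
        for d in range(3):
            force = np.zeros(fx.grid.shape)
            force[mask] = w * _sample(grads[..., d], mv.grid, mapped)
            corr = force
            for ax in range(3):
                corr = ndimage.correlate1d(corr, kernel, axis=ax, mode="constant")
            grad[..., d] = ndimage.map_coordinates(
                corr, ctrl_coords, order=1, mode="constant"
            ).reshape(nctrl)
        pen, pen_grad = penalty(coeffs)
        if pen_grad is not None:
            grad -= lam * pen_grad
        return ncc - lam * pen, grad

    step0 = stage.initial_step_vox * su
    c = ffd.coeffs

    def value_flat(cf):
        return value(cf.reshape(c.shape))

    def value_grad_flat(cf):
        v, g = value_grad(cf.reshape(c.shape))
        return v, g.reshape(-1)

    c_opt = _ascend(
        c.reshape(-1), value_flat, value_grad_flat, step0,
        stage.min_step_frac * step0, stage.iterations, trace,
        "deformable", stage_index, 0,
    )
    return BSplineFFD(
        ffd.origin_um, ffd.spacing_um, c_opt.reshape(c.shape),
        stage.control_spacing_vox,
    )


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def register_pairwise(
    fixed: Volume,
    moving: Volume,
    schedule: RegistrationSchedule,
    seed: int = 0,
) -> tuple[CompositeTransform, MetricTrace]:
    """Register ``moving`` onto ``fixed`` through the staged schedule.

    Returns the fixed→moving composite transform and the metric trace. The
    run is deterministic for a given input; ``seed`` is recorded for
    provenance (and would key any stochastic sampling, none by default).
    """
    del seed  # no stochastic sampling in the default configuration
    composite = CompositeTransform([])
    trace = MetricTrace()
    centre = fixed.grid.centre_um
    current = moving
    for si, stage in enumerate(schedule.stages):
        if isinstance(stage, LinearStageSpec):
            t = _optimize_linear(stage, fixed, current, centre, trace, si)
            composite.append(stage.kind, t)
        else:
            t = _optimize_deformable(stage, fixed, current, trace, si)
            composite.append("deformable", t)
        current = resample_volume(moving, composite, fixed.grid)
    return composite, trace


__all__ = [
    "PyramidLevel",
    "LinearStageSpec",
    "DeformableStageSpec",
    "RegistrationSchedule",
    "MetricTrace",
    "default_schedule",
    "compact_schedule",
    "ncc_metric",
    "register_pairwise",
]
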