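"""Iterative groupwise construction of a population-average volume.

A randomly chosen (or user-selected) specimen seeds the rigid pass: all other
specimens are rigidly registered onto it and the intensity-normalised warps
are averaged into a blurry rigid template. Because composing rigid
transforms only changes pose, this rigid average does not depend on which
specimen seeded it (up to a global pose). Subsequent passes re-register
every specimen to the current average with progressively richer transform
prefixes (… affine, then each B-spline control-spacing level), recomputing
the average after each pass, so the template sharpens as registration
becomes more local.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import Volume, normalize_intensity, resample_volume
from .errors import ParameterError, RegistrationError
from .registration import (
    DeformableStageSpec,
    MetricTrace,
    RegistrationSchedule,
    register_pairwise,
)
from .transforms import CompositeTransform

log = logging.getLogger(__name__)


@dataclass
class AverageBuildResult:
    average: Volume
    transforms: dict[int, CompositeTransform]
    residuals: list[float]  # mean abs intensity difference to the average, per pass
    log: dict = field(default_factory=dict)
    traces: dict[int, MetricTrace] = field(default_factory=dict)


def _pass_prefixes(schedule: RegistrationSchedule) -> list[RegistrationSchedule]:
    """One registration pass per stage-prefix: rigid first, then each
    further linear stage, then one pass per B-spline level."""
    return [schedule.prefix(n) for n in range(1, len(schedule.stages) + 1)]


def build_population_average(
    vols: list[Volume],
    schedule: RegistrationSchedule,
    seed_index: int | str = "random",
    seed: int = 0,
) -> AverageBuildResult:
    """Build a population average by iterative registration and averaging.

    ``seed_index`` selects the initial rigid target (``"random"`` draws it
    with ``seed``). Returns the final average (intensity-standardised), the
    final per-specimen transforms, and the per-pass mean-absolute residual.
    """
    if not vols:
        raise ParameterError("need at least one volume")
    grid = vols[0].grid
    if any(v.grid.spacing_um != grid.spacing_um for v in vols):
        raise ParameterError("all volumes must share a spacing")
    if seed_index == "random":
        seed_index = int(np.random.default_rng(seed).integers(len(vols)))
    if not 0 <= int(seed_index) < len(vols):
        raise ParameterError(f"seed_index {seed_index} out of range")
    seed_index = int(seed_index)

    if len(vols) == 1:
        avg = normalize_intensity(vols[0])
        return AverageBuildResult(
            avg, {0: CompositeTransform([])}, [0.0],
            {"n": 1, "seed_index": 0, "passes": 0},
        )

    target = normalize_intensity(vols[seed_index])
    transforms: dict[int, CompositeTransform] = {}
    traces: dict[int, MetricTrace] = {}
    residuals: list[float] = []
    passes = _pass_prefixes(schedule)
    for pi, prefix in enumerate(passes):
        warped = []
        for vi, vol in enumerate(vols):
            if pi == 0 and vi == seed_index:
                transforms[vi] = CompositeTransform([])
                traces[vi] = MetricTrace()
                warped.append(normalize_intensity(vol))
                continue
            try:
                t, tr = register_pairwise(target, vol, prefix, seed=seed)
            except RegistrationError as exc:
                raise RegistrationError(
                    f"specimen {vi} failed during pass {pi} "
                    f"({_pass_name(prefix)}): {exc}", getattr(exc, "trace", None),
                ) from exc
            transforms[vi] = t
            traces[vi] = tr
            warped.append(normalize_intensity(resample_volume(vol, t, grid)))
        avg_data = np.mean([w.data for w in warped], axis=0)
        target = Volume(grid, avg_data)
        residuals.append(
            float(np.mean([np.abs(w.data - avg_data).mean() for w in warped]))
        )
        log.info("average pass %d (%s): residual %.4f", pi, _pass_name(prefix), residuals[-1])
    return AverageBuildResult(
        target, transforms, residuals,
        {"n": len(vols), "seed_index": seed_index, "passes": len(passes)},
        traces,
    )


def _pass_name(prefix: RegistrationSchedule) -> str:
    last = prefix.stages[-1]
    if isinstance(last, DeformableStageSpec):
        return f"deformable@{last.control_spacing_vox:g}vox"
    return last.kind


__all__ = ["AverageBuildResult", "build_population_average"]
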