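"""Synthetic 3D embryo phantoms with ground truth.

A phantom is an ellipsoidal "body" containing disjoint spherical/ellipsoidal
"organs". A developmental-substage parameter ``s`` scales the body linearly
(so whole-embryo volume grows as ``s³``) while each organ's linear size
scales as ``s**a_k`` — organs with allometric exponent ``a_k > 1`` are
proportionally larger at later substages, ``a_k < 1`` proportionally
smaller, reproducing the substage confound that whole-embryo-volume
covariates must absorb. Genotype effects are per-organ volume multipliers
with incomplete penetrance (a Bernoulli draw per specimen) and variable
expressivity (a lognormal spread of the multiplier). Specimens receive a
random rigid pose and additive Gaussian noise; the label map is the
un-noised ground truth in the same pose.

Biological variability beyond substage is modelled as lognormal multiplicative
noise on organ volumes (default CV 8%, the low end of the organ-volume spread
reported for wild-type embryos after whole-volume normalisation) and 2% on
body volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ImageGrid, LabelInfo, LabelMap, Volume
from .errors import GenerationError, ParameterError
from .transforms import RigidTransform

log = logging.getLogger(__name__)

BODY_LABEL = 100  # envelope label; flagged is_whole_embryo in the atlas metadata
BASELINE_LINE = "baseline"
WT = "wt"
MUTANT = "mutant"


@dataclass(frozen=True)
class OrganSpec:
    """One organ: position/size relative to the body, allometry, intensity."""

    label_id: int
    centre_frac: tuple[float, float, float]  # relative to body semi-axes
    base_radius_frac: float  # fraction of the smallest body semi-axis (at s=1)
    allometric_exponent: float = 1.0
    intensity: float = 0.6
    sex_factor: float = 1.0  # volume multiplier applied to female specimens
    name: str = ""

    def __post_init__(self):
        if self.base_radius_frac <= 0:
            raise ParameterError("base_radius_frac must be positive")
        if not all(-1 < c < 1 for c in self.centre_frac):
            raise ParameterError("centre_frac components must lie in (-1, 1)")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and nuisance parameters of the phantom population."""

    grid: ImageGrid
    body_semi_axes_frac: tuple[float, float, float] = (0.78, 0.52, 0.52)
    organs: tuple[OrganSpec, ...] = ()
    s: float = 1.0  # developmental substage; 1 = nominal stage
    noise_sd: float = 0.02
    rotation_deg: float = 6.0
    translation_um: float = 28.0
    intensity_body: float = 0.35
    intensity_background: float = 0.02
    organ_volume_cv: float = 0.08  # biological spread of organ volumes
    body_volume_cv: float = 0.02

    def __post_init__(self):
        if self.s <= 0:
            raise ParameterError("substage s must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")

    def body_semi_axes_um(self, s: float | None = None) -> np.ndarray:
        s = self.s if s is None else s
        half_extent = (np.asarray(self.grid.shape) * self.grid.spacing_um) / 2.0
        return np.asarray(self.body_semi_axes_frac) * half_extent * s


@dataclass(frozen=True)
class LineEffect:
    """Per-line genotype effect: organ volume multipliers, penetrance,
    lognormal expressivity spread (sd on the log scale)."""

    line_id: str
    organ_effects: dict[int, float] = field(default_factory=dict)
    penetrance: dict[int, float] = field(default_factory=dict)
    expressivity_sd: float = 0.0

    def __post_init__(self):
        if any(e <= 0 for e in self.organ_effects.values()):
            raise ParameterError("organ effect multipliers must be positive")
        if any(not 0 <= p <= 1 for p in self.penetrance.values()):
            raise ParameterError("penetrance values must lie in [0, 1]")
        if self.expressivity_sd < 0:
            raise ParameterError("expressivity_sd must be non-negative")


def default_phantom_spec(
    shape: tuple[int, int, int] = (64, 64, 64), spacing_um: float = 14.0
) -> PhantomSpec:
    """Eight-organ phantom on a 64³ grid at nominal 14 μm spacing.

    Allometric exponents straddle 1 so normalised organ volumes trend both
    up and down with substage; organ 7 is the gonad analogue whose volume is
    halved in females.
    """
    organs = (
        OrganSpec(1, (-0.62, 0.0, 0.0), 0.30, 1.0, 0.62, name="head"),
        OrganSpec(2, (-0.28, 0.42, 0.0), 0.24, 1.3, 0.55, name="thymus"),
        OrganSpec(3, (-0.28, -0.42, 0.0), 0.24, 0.8, 0.70, name="ventricle"),
        OrganSpec(4, (0.0, 0.0, 0.45), 0.22, 1.1, 0.50, name="lung"),
        OrganSpec(5, (0.0, 0.0, -0.45), 0.22, 0.9, 0.66, name="gland"),
        OrganSpec(6, (0.30, 0.40, 0.0), 0.22, 1.0, 0.58, name="liver"),
        OrganSpec(7, (0.30, -0.40, 0.0), 0.20, 1.0, 0.72, 0.5, name="gonad"),
        OrganSpec(8, (0.64, 0.0, 0.0), 0.26, 1.2, 0.53, name="tail"),
    )
    return PhantomSpec(grid=ImageGrid(shape, spacing_um), organs=organs)


def phantom_label_info(spec: PhantomSpec) -> list[LabelInfo]:
    infos = [
        LabelInfo(o.label_id, o.name or f"organ_{o.label_id}")
        for o in spec.organs
    ]
    infos.append(LabelInfo(BODY_LABEL, "embryo body", is_whole_embryo=True))
    return infos


# ---------------------------------------------------------------------------
# analytic truth
# ---------------------------------------------------------------------------


def _organ_radius_um(spec: PhantomSpec, organ: OrganSpec, s: float) -> float:
    return organ.base_radius_frac * float(spec.body_semi_axes_um(1.0).min()) * (
        s**organ.allometric_exponent
    )


def _sphere_volume_mm3(radius_um: float) -> float:
    return (4.0 / 3.0) * np.pi * radius_um**3 * 1e-9


def _ellipsoid_volume_mm3(semi_axes_um: np.ndarray) -> float:
    return (4.0 / 3.0) * np.pi * float(np.prod(semi_axes_um)) * 1e-9


@dataclass
class SpecimenTruth:
    """Analytic per-specimen ground truth produced alongside each phantom."""

    specimen_id: str
    s: float
    sex: str
    wev_mm3: float
    organ_volumes_mm3: dict[int, float]
    effects_applied: dict[int, float]  # realised volume multiplier per organ

    def to_rows(self) -> list[dict]:
        return [
            {
                "specimen": self.specimen_id,
                "label": lab,
                "volume_mm3": v,
                "wev_mm3": self.wev_mm3,
                "s": self.s,
                "sex": self.sex,
                "effect_applied": self.effects_applied.get(lab, 1.0),
            }
            for lab, v in sorted(self.organ_volumes_mm3.items())
        ]


def _draw_specimen_multipliers(
    spec: PhantomSpec,
    effect: LineEffect | None,
    rng_bio: np.random.Generator,
    rng_eff: np.random.Generator,
    sex: str,
) -> tuple[dict[int, float], dict[int, float], float]:
    """Realised volume multipliers per organ, applied genotype effects, and
    the body-volume multiplier.

    Effect-stream draws are consumed for every organ whether or not an
    effect applies, so a zero-penetrance line reproduces the wild-type
    volumes of the same seed exactly.
    """
    multipliers: dict[int, float] = {}
    applied: dict[int, float] = {}
    for organ in spec.organs:
        m = float(np.exp(rng_bio.normal(0.0, spec.organ_volume_cv)))
        if sex.upper().startswith("F"):
            m *= organ.sex_factor
        # consume the effect stream deterministically for every organ
        hit = rng_eff.random()
        expr = rng_eff.normal(0.0, 1.0)
        if effect is not None and organ.label_id in effect.organ_effects:
            pi = effect.penetrance.get(organ.label_id, 1.0)
            if hit < pi:
                e = effect.organ_effects[organ.label_id] * float(
                    np.exp(expr * effect.expressivity_sd)
                )
                m *= e
                applied[organ.label_id] = e
        multipliers[organ.label_id] = m
    body_mult = float(np.exp(rng_bio.normal(0.0, spec.body_volume_cv)))
    return multipliers, applied, body_mult


def _check_geometry(
    spec: PhantomSpec, s: float, radii_um: dict[int, float]
) -> None:
    semi = spec.body_semi_axes_um(s)
    centres = {
        o.label_id: np.asarray(o.centre_frac) * semi for o in spec.organs
    }
    organs = list(spec.organs)
    for i, oi in enumerate(organs):
        ci, ri = centres[oi.label_id], radii_um[oi.label_id]
        # containment: the sphere must fit inside the body ellipsoid
        f = float(np.sqrt(np.sum((ci / semi) ** 2)))
        if f + ri / float(semi.min()) > 0.99:
            raise GenerationError(
                f"organ {oi.label_id} ({oi.name}) leaves the body at s={s:.3g}"
            )
        for oj in organs[i + 1 :]:
            cj, rj = centres[oj.label_id], radii_um[oj.label_id]
            if float(np.linalg.norm(ci - cj)) < ri + rj:
                raise GenerationError(
                    f"organs {oi.label_id} ({oi.name}) and {oj.label_id} "
                    f"({oj.name}) overlap at s={s:.3g}"
                )


def specimen_truth(
    spec: PhantomSpec,
    effect: LineEffect | None,
    seed: int,
    specimen_id: str = "spec",
    sex: str = "M",
) -> tuple[SpecimenTruth, dict[int, float], RigidTransform]:
    """Analytic truth table plus the realised radii and pose for one specimen."""
    ss = np.random.SeedSequence(int(seed))
    rng_pose, rng_noise, rng_bio, rng_eff = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    multipliers, applied, body_mult = _draw_specimen_multipliers(
        spec, effect, rng_bio, rng_eff, sex
    )
    s = spec.s
    radii = {
        o.label_id: _organ_radius_um(spec, o, s)
        * multipliers[o.label_id] ** (1.0 / 3.0)
        for o in spec.organs
    }
    _check_geometry(spec, s, radii)
    semi = spec.body_semi_axes_um(s) * body_mult ** (1.0 / 3.0)
    wev = _ellipsoid_volume_mm3(semi)
    volumes = {lab: _sphere_volume_mm3(r) for lab, r in radii.items()}

    angles = np.deg2rad(
        rng_pose.uniform(-spec.rotation_deg, spec.rotation_deg, size=3)
    )
    trans = rng_pose.uniform(-spec.translation_um, spec.translation_um, size=3)
    pose = RigidTransform(angles, trans, spec.grid.centre_um)
    truth = SpecimenTruth(specimen_id, s, sex, wev, volumes, applied)
    # stash the noise stream for the rasteriser
    truth._rng_noise = rng_noise  # type: ignore[attr-defined]
    truth._body_semi_um = semi  # type: ignore[attr-defined]
    return truth, radii, pose


def generate_specimen(
    spec: PhantomSpec,
    effect: LineEffect | None,
    seed: int,
    specimen_id: str = "spec",
    sex: str = "M",
    pose: bool = True,
) -> tuple[Volume, LabelMap, SpecimenTruth]:
    """Rasterise one phantom specimen.

    Returns the noisy grayscale image, the un-noised ground-truth label map
    in the same pose, and the analytic truth table (which also records the
    voxel-count volumes).
    """
    truth, radii, pose_t = specimen_truth(spec, effect, seed, specimen_id, sex)
    rng_noise = truth._rng_noise  # type: ignore[attr-defined]
    semi = truth._body_semi_um  # type: ignore[attr-defined]

    pts = spec.grid.voxel_centres().reshape(-1, 3)
    if pose:
        anat = pose_t.inverse().apply(pts) - spec.grid.centre_um
    else:
        anat = pts - spec.grid.centre_um

    data = np.full(len(pts), spec.intensity_background)
    labels = np.zeros(len(pts), dtype=np.int32)
    body = np.sum((anat / semi) ** 2, axis=1) <= 1.0
    data[body] = spec.intensity_body
    labels[body] = BODY_LABEL
    centres = {
        o.label_id: np.asarray(o.centre_frac) * spec.body_semi_axes_um(spec.s)
        for o in spec.organs
    }
    for organ in spec.organs:
        r = radii[organ.label_id]
        inside = np.sum((anat - centres[organ.label_id]) ** 2, axis=1) <= r * r
        data[inside] = organ.intensity
        labels[inside] = organ.label_id

    if spec.noise_sd > 0:
        data = data + rng_noise.normal(0.0, spec.noise_sd, size=data.shape)

    vol = Volume(spec.grid, data.reshape(spec.grid.shape))
    lmap = LabelMap(spec.grid, labels.reshape(spec.grid.shape))
    counts = np.bincount(labels, minlength=BODY_LABEL + 1)
    truth.voxel_volumes_mm3 = {  # type: ignore[attr-defined]
        o.label_id: float(counts[o.label_id]) * spec.grid.voxel_volume_mm3
        for o in spec.organs
    }
    truth.voxel_wev_mm3 = (  # type: ignore[attr-defined]
        float((labels > 0).sum()) * spec.grid.voxel_volume_mm3
    )
    return vol, lmap, truth


def phantom_atlas(spec: PhantomSpec) -> tuple[Volume, LabelMap, list[LabelInfo]]:
    """Noise-free, un-posed phantom at the spec's substage: the synthetic
    stand-in for a population average plus its hand-labelled atlas."""
    quiet = replace(
        spec, noise_sd=0.0, rotation_deg=0.0, translation_um=0.0,
        organ_volume_cv=0.0, body_volume_cv=0.0,
    )
    vol, labels, _ = generate_specimen(quiet, None, seed=0, pose=False)
    return vol, labels, phantom_label_info(spec)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def _cohort_plan(
    wt_n: int,
    substage_range: tuple[float, float],
    lines: list[tuple[LineEffect, int]],
    master_seed: int,
) -> list[dict]:
    """Deterministic specimen-level plan: ids, lines, substages, sexes, seeds."""
    if wt_n < 2:
        raise ParameterError("wt_n must be at least 2")
    lo, hi = substage_range
    if not 0 < lo <= hi:
        raise ParameterError("substage range must be positive with lo <= hi")
    ss = np.random.SeedSequence(int(master_seed))
    rng = np.random.default_rng(ss.spawn(1)[0])
    plan = []
    entries = [(BASELINE_LINE, None, wt_n)]
    for eff, n in lines:
        if n <= 0:
            log.warning("line %s has n=%d; excluded", eff.line_id, n)
            continue
        entries.append((eff.line_id, eff, n))
    for line_id, eff, n in entries:
        for k in range(n):
            plan.append(
                {
                    "specimen": f"{line_id}_{k:03d}",
                    "line": line_id,
                    "genotype": WT if eff is None else MUTANT,
                    "effect": eff,
                    "s": float(rng.uniform(lo, hi)),
                    "sex": "F" if rng.random() < 0.5 else "M",
                    "seed": int(rng.integers(0, 2**31 - 1)),
                }
            )
    return plan


def simulate_cohort_tables(
    spec: PhantomSpec,
    wt_n: int,
    substage_range: tuple[float, float],
    lines: list[tuple[LineEffect, int]],
    master_seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analytic cohort: specimen table and truth organ-volume table without
    rasterising any images. This is the fast path for statistics experiments
    where registration is bypassed and the truth tables stand in for
    propagated segmentations."""
    plan = _cohort_plan(wt_n, substage_range, lines, master_seed)
    truth_rows: list[dict] = []
    spec_rows: list[dict] = []
    for p in plan:
        sspec = replace(spec, s=p["s"])
        truth, _, _ = specimen_truth(
            sspec, p["effect"], p["seed"], p["specimen"], p["sex"]
        )
        truth_rows.extend(truth.to_rows())
        spec_rows.append(
            {k: p[k] for k in ("specimen", "line", "genotype", "sex")}
        )
    return pd.DataFrame(spec_rows), pd.DataFrame(truth_rows)


def generate_cohort(
    out_dir: str | Path,
    spec: PhantomSpec,
    wt_n: int,
    substage_range: tuple[float, float],
    lines: list[tuple[LineEffect, int]],
    master_seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rasterise a cohort to disk: NRRD volumes + truth/specimen CSVs.

    Per-specimen seeds derive deterministically from ``master_seed``, so the
    same seed reproduces the dataset byte for byte.
    """
    from . import io as eio

    out_dir = Path(out_dir)
    (out_dir / "volumes").mkdir(parents=True, exist_ok=True)
    (out_dir / "labels").mkdir(parents=True, exist_ok=True)
    plan = _cohort_plan(wt_n, substage_range, lines, master_seed)
    truth_rows: list[dict] = []
    spec_rows: list[dict] = []
    for p in plan:
        sspec = replace(spec, s=p["s"])
        vol, lmap, truth = generate_specimen(
            sspec, p["effect"], p["seed"], p["specimen"], p["sex"]
        )
        eio.write_volume(out_dir / "volumes" / f"{p['specimen']}.nrrd", vol)
        eio.write_labels(out_dir / "labels" / f"{p['specimen']}.nrrd", lmap)
        truth_rows.extend(truth.to_rows())
        spec_rows.append({k: p[k] for k in ("specimen", "line", "genotype", "sex")})
    specimens = pd.DataFrame(spec_rows)
    truth = pd.DataFrame(truth_rows)
    specimens.to_csv(out_dir / "specimens.csv", index=False)
    truth.to_csv(out_dir / "truth.csv", index=False)
    eio.write_label_info(out_dir / "labels.csv", phantom_label_info(spec))
    (out_dir / "phantom_spec.toml").write_text(_spec_to_toml(spec, master_seed))
    return specimens, truth


def _spec_to_toml(spec: PhantomSpec, master_seed: int) -> str:
    """Serialise the phantom spec (provenance record written with cohorts)."""
    lines = [
        "[phantom]",
        f"shape = {list(spec.grid.shape)}",
        f"spacing_um = {spec.grid.spacing_um}",
        f"body_semi_axes_frac = {list(spec.body_semi_axes_frac)}",
        f"s = {spec.s}",
        f"noise_sd = {spec.noise_sd}",
        f"rotation_deg = {spec.rotation_deg}",
        f"translation_um = {spec.translation_um}",
        f"organ_volume_cv = {spec.organ_volume_cv}",
        f"body_volume_cv = {spec.body_volume_cv}",
        f"master_seed = {master_seed}",
        "",
    ]
    for o in spec.organs:
        lines += [
            "[[organ]]",
            f"label_id = {o.label_id}",
            f'name = "{o.name}"',
            f"centre_frac = {list(o.centre_frac)}",
            f"base_radius_frac = {o.base_radius_frac}",
            f"allometric_exponent = {o.allometric_exponent}",
            f"intensity = {o.intensity}",
            f"sex_factor = {o.sex_factor}",
            "",
        ]
    return "\n".join(lines)


def truth_to_organ_table(
    specimens: pd.DataFrame, truth: pd.DataFrame
) -> pd.DataFrame:
    """Convert a truth table into the organ-volume table the statistics
    module consumes (normalised volumes and wild-type WEV z-scores)."""
    df = truth.merge(
        specimens[["specimen", "line", "genotype", "sex"]], on="specimen", how="left",
        suffixes=("", "_spec"),
    )
    df["normalized_volume"] = df["volume_mm3"] / df["wev_mm3"]
    wt_wev = df.loc[df["genotype"] == WT].groupby("specimen")["wev_mm3"].first()
    mu, sd = float(wt_wev.mean()), float(wt_wev.std(ddof=1))
    df["wev_zscore"] = (df["wev_mm3"] - mu) / sd if sd > 0 else 0.0
    cols = [
        "specimen", "line", "genotype", "sex", "label",
        "volume_mm3", "wev_mm3", "normalized_volume", "wev_zscore",
    ]
    return df[cols]


__all__ = [
    "BODY_LABEL",
    "BASELINE_LINE",
    "WT",
    "MUTANT",
    "OrganSpec",
    "PhantomSpec",
    "LineEffect",
    "default_phantom_spec",
    "phantom_label_info",
    "phantom_atlas",
    "specimen_truth",
    "generate_specimen",
    "generate_cohort",
    "simulate_cohort_tables",
    "truth_to_organ_table",
]
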