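"""End-to-end orchestration: TOML configuration, staged runs, QC reporting.

A run directory is laid out as::

    <output_root>/
      average/            population average (built or copied)
      registrations/<id>/ transform JSON, warped image, metric trace CSV
      jacobians/          deformable-only determinant fields (NRRD)
      inverted_labels/    specimen-space segmentations (NRRD)
      stats/              organ table, thresholds, calls, staging CSVs
      qc/                 HTML report + montage/trace PNGs
      run_log.json        seeds, schedule, QC counts

Stages write a ``.done.json`` marker and are skipped on re-run unless
``force`` is set, so interrupted runs resume where they stopped.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as eio
from .core import foreground_mask, resample_volume
from .errors import ConfigError
from .jacobian import jacobian_determinant_field, negative_jacobian_report
from .phantom import WT
from .population import build_population_average
from .propagation import organ_volume_table, propagate_labels
from .registration import (
    compact_schedule,
    default_schedule,
    ncc_metric,
    register_pairwise,
)
from .stats import gene_level_calls, specimen_level_calls, staging_report
from .transforms import save_transform

log = logging.getLogger(__name__)

STAGES = ("average", "register", "organ_table", "stats", "qc")


@dataclass
class PipelineConfig:
    """Validated run configuration (see ``example_config`` for the schema)."""

    output_root: Path
    volumes_dir: Path
    specimens_csv: Path
    atlas_labels: Path
    atlas_meta: Path
    average_path: Path | None = None
    spacing_um: float | None = None
    schedule_name: str = "compact"
    include_similarity: bool = True
    control_spacings: tuple[float, ...] = (16.0, 8.0)
    iterations_linear: int = 80
    iterations_deformable: int = 60
    alpha: float = 0.05
    gene_fdr: float = 0.05
    specimen_fdr: float = 0.20
    n_perms: int = 500
    include_wev: bool = True
    seed: int = 0
    thin_cutoff: float = 1.5
    qc_enabled: bool = True

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        paths = raw.get("paths", {})
        reg = raw.get("registration", {})
        st = raw.get("stats", {})
        qc = raw.get("qc", {})

        def _p(key, required=True):
            if key not in paths:
                if required:
                    raise ConfigError(f"[paths] missing required key {key!r}")
                return None
            p = Path(paths[key])
            if not p.is_absolute():
                p = path.parent / p
            return p

        cfg = cls(
            output_root=_p("output_root"),
            volumes_dir=_p("volumes_dir"),
            specimens_csv=_p("specimens_csv"),
            atlas_labels=_p("atlas_labels"),
            atlas_meta=_p("atlas_meta"),
            average_path=_p("average", required=False),
            spacing_um=raw.get("spacing_um"),
            schedule_name=reg.get("schedule", "compact"),
            include_similarity=reg.get("include_similarity", True),
            control_spacings=tuple(reg.get("control_spacings", (16.0, 8.0))),
            iterations_linear=int(reg.get("iterations_linear", 80)),
            iterations_deformable=int(reg.get("iterations_deformable", 60)),
            alpha=float(st.get("alpha", 0.05)),
            gene_fdr=float(st.get("gene_fdr", 0.05)),
            specimen_fdr=float(st.get("specimen_fdr", 0.20)),
            n_perms=int(st.get("n_perms", 500)),
            include_wev=bool(st.get("include_wev", True)),
            seed=int(st.get("seed", raw.get("seed", 0))),
            thin_cutoff=float(st.get("thin_cutoff", 1.5)),
            qc_enabled=bool(qc.get("enabled", True)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("volumes_dir", "specimens_csv", "atlas_labels", "atlas_meta"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise ConfigError(f"configured path {name}={p} does not exist")
        if self.average_path is not None and not Path(self.average_path).exists():
            raise ConfigError(f"average path {self.average_path} does not exist")

    def schedule(self):
        if self.schedule_name == "default":
            return default_schedule(include_similarity=self.include_similarity)
        return compact_schedule(
            control_spacings=self.control_spacings,
            iterations_linear=self.iterations_linear,
            iterations_deformable=self.iterations_deformable,
            include_similarity=self.include_similarity,
        )


EXAMPLE_CONFIG = """\
# embryomorph run configuration
[paths]
output_root = "run"            # created if absent
volumes_dir = "data/volumes"   # one NRRD/NIfTI/TIFF volume per specimen
specimens_csv = "data/specimens.csv"  # columns: specimen,line,genotype[,sex]
atlas_labels = "data/atlas_labels.nrrd"
atlas_meta = "data/labels.csv" # columns: label,name,ontology_id,is_thin,is_whole_embryo
# average = "data/average.nrrd"  # omit to build one from the baselines

[registration]
schedule = "compact"           # or "default" (5 B-spline levels ending at 8 voxels)
include_similarity = true
control_spacings = [16.0, 8.0]
iterations_linear = 80
iterations_deformable = 60

[stats]
alpha = 0.05
gene_fdr = 0.05
specimen_fdr = 0.20
n_perms = 500
include_wev = true
seed = 0

[qc]
enabled = true
"""


# ---------------------------------------------------------------------------
# stage plumbing
# ---------------------------------------------------------------------------


def _marker(out_root: Path, stage: str) -> Path:
    return out_root / f"{stage}.done.json"


def _stage_done(out_root: Path, stage: str) -> bool:
    return _marker(out_root, stage).exists()


def _mark_done(out_root: Path, stage: str, info: dict) -> None:
    _marker(out_root, stage).write_text(json.dumps(info))


def run_pipeline(
    config: PipelineConfig, force: bool = False, stop_after: str | None = None
) -> Path:
    """Execute stages in dependency order up to ``stop_after`` (default:
    all); completed stages are skipped on re-run unless ``force``. Returns
    the run directory."""
    if stop_after is not None and stop_after not in STAGES:
        raise ConfigError(f"stop_after must be one of {STAGES}")
    config.validate()
    out = Path(config.output_root)
    out.mkdir(parents=True, exist_ok=True)
    specimens = eio.read_specimen_table(config.specimens_csv)
    atlas_labels = eio.read_labels(config.atlas_labels, config.spacing_um)
    atlas_meta = eio.read_label_info(config.atlas_meta)
    schedule = config.schedule()
    run_log = {
        "seed": config.seed,
        "n_specimens": len(specimens),
        "schedule": _schedule_summary(schedule),
        "stages_run": [],
        "stages_skipped": [],
    }

    # --- population average ------------------------------------------------
    avg_file = out / "average" / "population_average.nrrd"
    if _stage_done(out, "average") and not force:
        run_log["stages_skipped"].append("average")
        average = eio.read_volume(avg_file, config.spacing_um)
    else:
        if config.average_path is not None:
            average = eio.read_volume(config.average_path, config.spacing_um)
        else:
            baselines = specimens[specimens["genotype"] == WT]
            vols = [
                eio.read_volume(
                    Path(config.volumes_dir) / f"{s}.nrrd", config.spacing_um
                )
                for s in baselines["specimen"]
            ]
            average = build_population_average(
                vols, schedule, seed_index="random", seed=config.seed
            ).average
        eio.write_volume(avg_file, average)
        _mark_done(out, "average", {"built": config.average_path is None})
        run_log["stages_run"].append("average")
    if average.grid != atlas_labels.grid:
        raise ConfigError("atlas labels and average are on different grids")
    if stop_after == "average":
        (out / "run_log.json").write_text(json.dumps(run_log, indent=1))
        return out

    # --- per-specimen registration / propagation / jacobians ---------------
    mask = foreground_mask(average)
    qc_rows = []
    if _stage_done(out, "register") and not force:
        run_log["stages_skipped"].append("register")
        qc_rows = json.loads((out / "qc_rows.json").read_text())
    else:
        for spec_id in specimens["specimen"]:
            reg_dir = out / "registrations" / str(spec_id)
            reg_dir.mkdir(parents=True, exist_ok=True)
            vol = eio.read_volume(
                Path(config.volumes_dir) / f"{spec_id}.nrrd", config.spacing_um
            )
            transform, trace = register_pairwise(
                average, vol, schedule, seed=config.seed
            )
            save_transform(reg_dir / "transform.json", transform)
            trace.to_csv(reg_dir / "metric_trace.csv")
            warped = resample_volume(vol, transform, average.grid)
            eio.write_volume(reg_dir / "registered.nrrd", warped)

            jf = jacobian_determinant_field(
                transform, average.grid, specimen_id=str(spec_id)
            )
            neg_count, _ = negative_jacobian_report(jf)
            eio.write_volume(out / "jacobians" / f"{spec_id}.nrrd", jf.volume)

            seg = propagate_labels(atlas_labels, transform, vol.grid)
            eio.write_labels(out / "inverted_labels" / f"{spec_id}.nrrd", seg)
            qc_rows.append(
                {
                    "specimen": str(spec_id),
                    "final_ncc": float(ncc_metric(average, warped, mask)),
                    "negative_jacobians": int(neg_count),
                    "registration_ok": bool(neg_count == 0),
                }
            )
            log.info(
                "registered %s: ncc=%.4f, negative dets=%d",
                spec_id, qc_rows[-1]["final_ncc"], neg_count,
            )
        (out / "qc_rows.json").write_text(json.dumps(qc_rows))
        _mark_done(out, "register", {"n": len(qc_rows)})
        run_log["stages_run"].append("register")
    if stop_after == "register":
        run_log["qc"] = qc_rows
        (out / "run_log.json").write_text(json.dumps(run_log, indent=1))
        return out

    # --- organ volumes ------------------------------------------------------
    table_file = out / "stats" / "organ_volumes.csv"
    if _stage_done(out, "organ_table") and not force:
        run_log["stages_skipped"].append("organ_table")
        table = pd.read_csv(table_file)
    else:
        segs = {
            str(s): eio.read_labels(
                out / "inverted_labels" / f"{s}.nrrd", config.spacing_um
            )
            for s in specimens["specimen"]
        }
        from .core import flag_thin_labels

        thin = flag_thin_labels(atlas_labels, config.thin_cutoff)
        table = organ_volume_table(segs, atlas_meta, specimens, thin)
        (out / "stats").mkdir(parents=True, exist_ok=True)
        table.to_csv(table_file, index=False)
        _mark_done(out, "organ_table", {"thin_excluded": sorted(thin)})
        run_log["stages_run"].append("organ_table")

    # --- statistics ---------------------------------------------------------
    if stop_after == "organ_table":
        run_log["qc"] = qc_rows
        (out / "run_log.json").write_text(json.dumps(run_log, indent=1))
        return out
    if _stage_done(out, "stats") and not force:
        run_log["stages_skipped"].append("stats")
    else:
        stats_dir = out / "stats"
        stats_dir.mkdir(parents=True, exist_ok=True)
        gene_calls, thresholds, _ = gene_level_calls(
            table, config.n_perms, config.seed, config.gene_fdr, config.include_wev
        )
        spec_calls, spec_thr, _ = specimen_level_calls(
            table, config.n_perms, config.seed, config.specimen_fdr, config.include_wev
        )
        if not gene_calls.empty:
            gene_calls.to_csv(stats_dir / "gene_calls.csv", index=False)
            thresholds.to_csv(stats_dir / "gene_thresholds.csv", index=False)
        if not spec_calls.empty:
            spec_calls.to_csv(stats_dir / "specimen_calls.csv", index=False)
            spec_thr.to_csv(stats_dir / "specimen_thresholds.csv", index=False)
        baselines = table[table["genotype"] == WT]
        if baselines["specimen"].nunique() >= 4:
            staging_report(baselines, config.alpha).to_csv(
                stats_dir / "staging.csv", index=False
            )
        _mark_done(out, "stats", {"n_perms": config.n_perms})
        run_log["stages_run"].append("stats")

    # --- QC report ----------------------------------------------------------
    if config.qc_enabled and stop_after not in ("organ_table", "stats"):
        if _stage_done(out, "qc") and not force:
            run_log["stages_skipped"].append("qc")
        else:
            generate_qc_report(out)
            _mark_done(out, "qc", {})
            run_log["stages_run"].append("qc")

    run_log["qc"] = qc_rows
    (out / "run_log.json").write_text(json.dumps(run_log, indent=1))
    return out


def _schedule_summary(schedule) -> dict:
    from .registration import DeformableStageSpec

    return {
        "stages": [
            {
                "kind": s.kind,
                **(
                    {"control_spacing_vox": s.control_spacing_vox}
                    if isinstance(s, DeformableStageSpec)
                    else {}
                ),
            }
            for s in schedule.stages
        ],
        "finest_control_spacing_vox": schedule.finest_control_spacing_vox,
    }


# ---------------------------------------------------------------------------
# QC report
# ---------------------------------------------------------------------------


def generate_qc_report(run_dir: str | Path) -> Path:
    """HTML report with mid-sagittal montage tiles, metric-versus-iteration
    plots and negative-Jacobian flags for every registered specimen."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    qc_dir = run_dir / "qc"
    qc_dir.mkdir(parents=True, exist_ok=True)
    reg_root = run_dir / "registrations"
    specimens = sorted(p.name for p in reg_root.iterdir()) if reg_root.exists() else []
    qc_rows = {}
    rows_file = run_dir / "qc_rows.json"
    if rows_file.exists():
        qc_rows = {r["specimen"]: r for r in json.loads(rows_file.read_text())}

    tiles = []
    for spec_id in specimens:
        reg_dir = reg_root / spec_id
        img_file = reg_dir / "registered.nrrd"
        tile_png = qc_dir / f"{spec_id}_sagittal.png"
        if img_file.exists():
            vol = eio.read_volume(img_file)
            mid = vol.data[:, :, vol.grid.shape[2] // 2]
            fig, ax = plt.subplots(figsize=(2.2, 2.2))
            ax.imshow(mid, cmap="gray")
            ax.set_title(spec_id, fontsize=7)
            ax.axis("off")
            fig.savefig(tile_png, dpi=80, bbox_inches="tight")
            plt.close(fig)
        trace_file = reg_dir / "metric_trace.csv"
        trace_png = qc_dir / f"{spec_id}_trace.png"
        if trace_file.exists():
            df = pd.read_csv(trace_file)
            fig, ax = plt.subplots(figsize=(3.2, 2.2))
            for (stage, si), grp in df.groupby(["stage", "stage_index"]):
                ax.plot(grp["metric"].to_numpy(), label=f"{stage}[{si}]", lw=0.8)
            ax.set_xlabel("iteration")
            ax.set_ylabel("NCC")
            ax.legend(fontsize=5)
            fig.savefig(trace_png, dpi=80, bbox_inches="tight")
            plt.close(fig)
        row = qc_rows.get(spec_id, {})
        neg = row.get("negative_jacobians", 0)
        tiles.append(
            f"<div class='tile'><h3>{spec_id}</h3>"
            f"<img src='{tile_png.name}'/><img src='{trace_png.name}'/>"
            f"<p>NCC: {row.get('final_ncc', float('nan')):.4f} — "
            f"negative Jacobians: {neg}"
            + (" <b class='warn'>FOLDING</b>" if neg else "")
            + "</p></div>"
        )

    body = "\n".join(tiles) if tiles else "<p><b>No specimens registered.</b></p>"
    html = (
        "<html><head><title>registration QC</title><style>"
        ".tile{display:inline-block;margin:6px;border:1px solid #ccc;padding:4px}"
        ".warn{color:#c00}</style></head><body>"
        f"<h1>Registration QC ({len(tiles)} specimens)</h1>{body}</body></html>"
    )
    report = qc_dir / "qc_report.html"
    report.write_text(html)
    return report


__all__ = [
    "PipelineConfig",
    "EXAMPLE_CONFIG",
    "run_pipeline",
    "generate_qc_report",
    "STAGES",
]
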