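"""Reading and writing volumes, label maps and metadata tables.

NRRD is the canonical on-disk format (gzip encoded, header carries spacing
and origin); NIfTI-1 and multi-page TIFF are accepted on input. Spacing
conflicts between file headers and a configured spacing are resolved in
favour of the configuration with a logged warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

from .core import ImageGrid, LabelInfo, LabelMap, Volume, validate_label_info
from .errors import GridError

log = logging.getLogger(__name__)

_NRRD_SUFFIXES = {".nrrd", ".nhdr"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


def _grid_from_sitk(img: sitk.Image, spacing_override: float | None) -> ImageGrid:
    spacing_xyz = np.asarray(img.GetSpacing())
    origin_xyz = np.asarray(img.GetOrigin())
    shape_zyx = tuple(int(s) for s in reversed(img.GetSize()))
    if spacing_override is not None:
        if not np.allclose(spacing_xyz, spacing_override):
            log.warning(
                "header spacing %s overridden by configured spacing %s",
                spacing_xyz,
                spacing_override,
            )
        spacing = float(spacing_override)
    else:
        if not np.allclose(spacing_xyz, spacing_xyz[0]):
            raise GridError(f"non-isotropic spacing {spacing_xyz}")
        spacing = float(spacing_xyz[0])
    return ImageGrid(shape_zyx, spacing, tuple(reversed(origin_xyz.tolist())))


def _read_array_grid(path: Path, spacing_override: float | None):
    suffix = "".join(path.suffixes[-2:]) if path.name.endswith(".nii.gz") else path.suffix
    suffix = suffix.lower()
    if suffix in _NRRD_SUFFIXES:
        img = sitk.ReadImage(str(path))
        return sitk.GetArrayFromImage(img), _grid_from_sitk(img, spacing_override)
    if suffix in {".nii", ".nii.gz"}:
        img = nib.load(str(path))
        data_xyz = np.asanyarray(img.dataobj)
        if data_xyz.ndim != 3:
            raise GridError(f"expected a 3D NIfTI volume, got shape {data_xyz.shape}")
        zooms = img.header.get_zooms()[:3]
        if spacing_override is not None:
            if not np.allclose(zooms, spacing_override):
                log.warning(
                    "NIfTI zooms %s overridden by configured spacing %s",
                    zooms,
                    spacing_override,
                )
            spacing = float(spacing_override)
        else:
            if not np.allclose(zooms, zooms[0]):
                raise GridError(f"non-isotropic NIfTI zooms {zooms}")
            spacing = float(zooms[0])
        return np.transpose(data_xyz, (2, 1, 0)), ImageGrid(
            tuple(reversed(data_xyz.shape)), spacing
        )
    if suffix in _TIFF_SUFFIXES:
        data = tifffile.imread(str(path))
        if data.ndim != 3:
            raise GridError(f"expected a 3D TIFF stack, got shape {data.shape}")
        if spacing_override is None:
            log.warning("TIFF carries no spacing; assuming 1.0 μm (pass a spacing)")
            spacing = 1.0
        else:
            spacing = float(spacing_override)
        return data, ImageGrid(tuple(data.shape), spacing)
    raise GridError(f"unsupported volume format: {path.name}")


def read_volume(path: str | Path, spacing_um: float | None = None) -> Volume:
    data, grid = _read_array_grid(Path(path), spacing_um)
    return Volume(grid, np.asarray(data, dtype=np.float64))


def read_labels(path: str | Path, spacing_um: float | None = None) -> LabelMap:
    data, grid = _read_array_grid(Path(path), spacing_um)
    return LabelMap(grid, np.asarray(np.round(data), dtype=np.int32))


def _to_sitk(data: np.ndarray, grid: ImageGrid) -> sitk.Image:
    img = sitk.GetImageFromArray(data)
    img.SetSpacing((grid.spacing_um,) * 3)
    img.SetOrigin(tuple(reversed(grid.origin_um)))
    return img


def write_volume(path: str | Path, vol: Volume) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(_to_sitk(vol.data.astype(np.float32), vol.grid), str(path), True)


def write_labels(path: str | Path, labels: LabelMap) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(
        _to_sitk(labels.data.astype(np.uint16), labels.grid), str(path), True
    )


# ---------------------------------------------------------------------------
# label metadata and specimen tables
# ---------------------------------------------------------------------------

LABEL_INFO_COLUMNS = ["label", "name", "ontology_id", "is_thin", "is_whole_embryo"]


def read_label_info(path: str | Path) -> list[LabelInfo]:
    df = pd.read_csv(path, dtype={"ontology_id": str}, keep_default_na=False)
    missing = set(LABEL_INFO_COLUMNS) - set(df.columns)
    if missing:
        raise GridError(f"label metadata missing columns: {sorted(missing)}")
    infos = [
        LabelInfo(
            label_id=int(r["label"]),
            name=str(r["name"]),
            ontology_id=str(r["ontology_id"]),
            is_thin=_as_bool(r["is_thin"]),
            is_whole_embryo=_as_bool(r["is_whole_embryo"]),
        )
        for _, r in df.iterrows()
    ]
    validate_label_info(infos)
    return infos


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in {"true", "1", "yes"}
    return bool(v)


def write_label_info(path: str | Path, infos: list[LabelInfo]) -> None:
    validate_label_info(infos)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "label": [i.label_id for i in infos],
            "name": [i.name for i in infos],
            "ontology_id": [i.ontology_id for i in infos],
            "is_thin": [i.is_thin for i in infos],
            "is_whole_embryo": [i.is_whole_embryo for i in infos],
        }
    ).to_csv(path, index=False)


def read_specimen_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"specimen", "line", "genotype"}
    missing = required - set(df.columns)
    if missing:
        raise GridError(f"specimen table missing columns: {sorted(missing)}")
    if "sex" not in df.columns:
        df["sex"] = ""
    return df


__all__ = [
    "read_volume",
    "read_labels",
    "write_volume",
    "write_labels",
    "read_label_info",
    "write_label_info",
    "read_specimen_table",
    "LABEL_INFO_COLUMNS",
]
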