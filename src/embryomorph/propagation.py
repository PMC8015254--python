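"""Atlas label propagation and organ-volume tables.

Each specimen is segmented automatically by carrying the atlas labels from
population-average space into specimen space through the inverse of the
specimen's registration transform (nearest-neighbour, background where the
inverse leaves the atlas). Organ volumes are voxel counts × spacing³
(reported in mm³); the whole-embryo volume (WEV) is the volume of the
embryo envelope — the union of all foreground labels, anchored by the
atlas's ``is_whole_embryo`` entry — and each specimen's WEV z-score is
computed against the wild-type WEV distribution so that developmentally
delayed outliers can be spotted and excluded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import ImageGrid, LabelInfo, LabelMap, resample_labels, validate_label_info
from .errors import ParameterError
from .phantom import WT
from .transforms import SpatialTransform, invert_transform

log = logging.getLogger(__name__)


def propagate_labels(
    atlas: LabelMap,
    transform: SpatialTransform,
    specimen_grid: ImageGrid,
    tol_um: float | None = None,
) -> LabelMap:
    """Specimen-space segmentation from the fixed→moving registration
    transform: label at specimen voxel ``x`` = atlas label at ``T⁻¹(x)``."""
    inverse = invert_transform(transform, atlas.grid, tol_um=tol_um)
    return resample_labels(atlas, inverse, specimen_grid)


def organ_volume_table(
    segmentations: dict[str, LabelMap],
    atlas_meta: list[LabelInfo],
    specimens: pd.DataFrame,
    thin_label_ids: set[int] | None = None,
) -> pd.DataFrame:
    """Per specimen × organ volume table (mm³) with WEV, normalised volumes
    and wild-type WEV z-scores.

    Labels flagged thin in the metadata (or passed in ``thin_label_ids``)
    are excluded; a label absent from a specimen's segmentation gets volume
    0 with a logged warning.
    """
    validate_label_info(atlas_meta)
    whole = [i for i in atlas_meta if i.is_whole_embryo]
    if not whole:
        raise ParameterError("atlas metadata has no is_whole_embryo label")
    excluded = {i.label_id for i in atlas_meta if i.is_thin}
    if thin_label_ids:
        excluded |= set(thin_label_ids)
    organ_ids = [
        i.label_id
        for i in atlas_meta
        if not i.is_whole_embryo and i.label_id not in excluded
    ]

    meta = specimens.set_index("specimen")
    rows = []
    for spec_id, seg in segmentations.items():
        vox_mm3 = seg.grid.voxel_volume_mm3
        counts = np.bincount(seg.data.reshape(-1))
        wev = float((seg.data > 0).sum()) * vox_mm3
        if wev <= 0:
            raise ParameterError(
                f"specimen {spec_id}: empty segmentation, no whole-embryo volume"
            )
        for lab in organ_ids:
            n = int(counts[lab]) if lab < len(counts) else 0
            if n == 0:
                log.warning("specimen %s: label %d absent (volume 0)", spec_id, lab)
            vol = n * vox_mm3
            rows.append(
                {
                    "specimen": spec_id,
                    "line": meta.loc[spec_id, "line"],
                    "genotype": meta.loc[spec_id, "genotype"],
                    "sex": meta.loc[spec_id].get("sex", ""),
                    "label": lab,
                    "volume_mm3": vol,
                    "wev_mm3": wev,
                    "normalized_volume": vol / wev,
                }
            )
    table = pd.DataFrame(rows)
    wt_wev = table.loc[table["genotype"] == WT].groupby("specimen")["wev_mm3"].first()
    if len(wt_wev) >= 2 and float(wt_wev.std(ddof=1)) > 0:
        mu, sd = float(wt_wev.mean()), float(wt_wev.std(ddof=1))
        table["wev_zscore"] = (table["wev_mm3"] - mu) / sd
    else:
        table["wev_zscore"] = 0.0
    return table


def dice_coefficient(a: LabelMap, b: LabelMap, label_id: int) -> float:
    """Dice overlap of one label between two label maps on the same grid."""
    ma = a.data == label_id
    mb = b.data == label_id
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return np.nan
    return 2.0 * int((ma & mb).sum()) / denom


__all__ = ["propagate_labels", "organ_volume_table", "dice_coefficient"]
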