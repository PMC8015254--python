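"""Shared fixtures.

The expensive registration fixtures are module-scoped and reused by the
registration, propagation and acceptance tests so the full suite stays
within a desk-scale runtime.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from embryomorph.core import ImageGrid, Volume
from embryomorph.phantom import default_phantom_spec, generate_specimen, phantom_atlas
from embryomorph.registration import compact_schedule, register_pairwise


@pytest.fixture(scope="session")
def grid16():
    return ImageGrid((16, 16, 16), spacing_um=14.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def phantom_spec64():
    return default_phantom_spec((64, 64, 64))


@pytest.fixture(scope="session")
def atlas64(phantom_spec64):
    """Noise-free un-posed phantom: (volume, labels, metadata)."""
    return phantom_atlas(phantom_spec64)


@pytest.fixture(scope="session")
def smooth_blob48():
    """Band-limited blob image for interpolation/registration checks."""
    grid = ImageGrid((48, 48, 48), spacing_um=14.0)
    z, y, x = np.meshgrid(*[np.arange(48)] * 3, indexing="ij")
    c = 23.5
    r2 = ((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2) / 14.0**2
    data = np.exp(-r2 / 2.0) + 0.4 * np.exp(
        -((z - 30.0) ** 2 + (y - 18.0) ** 2 + (x - 25.0) ** 2) / 50.0
    )
    return Volume(grid, data)


@pytest.fixture(scope="session")
def registered_phantom(phantom_spec64, atlas64):
    """One posed, substage-shifted, noise-free specimen registered to the
    phantom atlas with the compact two-level B-spline schedule.

    Returns a dict with the atlas, specimen, truth, composite transform and
    metric trace; shared by every test that needs a realistic registration.
    """
    atlas_vol, atlas_labels, meta = atlas64
    sspec = replace(phantom_spec64, noise_sd=0.0, s=1.05)
    vol, truth_labels, truth = generate_specimen(sspec, None, seed=11)
    schedule = compact_schedule(
        control_spacings=(16.0, 8.0),
        iterations_linear=80,
        iterations_deformable=60,
        include_similarity=True,
    )
    transform, trace = register_pairwise(atlas_vol, vol, schedule)
    return {
        "atlas_vol": atlas_vol,
        "atlas_labels": atlas_labels,
        "meta": meta,
        "specimen": vol,
        "truth_labels": truth_labels,
        "truth": truth,
        "transform": transform,
        "trace": trace,
        "schedule": schedule,
    }
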