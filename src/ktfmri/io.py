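"""Export/import helpers: NIfTI-1 magnitude volumes and array containers.

Complex data cannot ride in a plain NIfTI magnitude export, so series are
written twice: a NIfTI-1 file holding |u| for viewing in standard tools,
and an ``.npz`` container holding the complex frames plus paradigm and
provenance metadata for lossless round trips.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

from .containers import ImageSeries, Paradigm

__all__ = ["series_to_nifti", "save_series", "load_series", "map_to_nifti"]


def series_to_nifti(series: ImageSeries, path, voxel_size_mm: float = 1.0) -> None:
    """Write the magnitude stack as a NIfTI-1 volume (x, y, t)."""
    affine = np.diag([voxel_size_mm, voxel_size_mm, 1.0, 1.0])
    img = nib.Nifti1Image(series.magnitude().astype(np.float32), affine)
    nib.save(img, str(path))


def map_to_nifti(arr: np.ndarray, path, voxel_size_mm: float = 1.0) -> None:
    """Write a 2D map (t-scores, masks, ...) as a single-slice NIfTI-1."""
    affine = np.diag([voxel_size_mm, voxel_size_mm, 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32)[:, :, None], affine)
    nib.save(img, str(path))


def save_series(series: ImageSeries, path) -> None:
    """Lossless complex container with paradigm/provenance metadata."""
    meta = {"provenance": series.provenance}
    if series.paradigm is not None:
        meta["paradigm"] = [
            series.paradigm.n_pre,
            series.paradigm.n_stim,
            series.paradigm.n_post,
        ]
    np.savez_compressed(
        path, frames=series.frames, meta=np.frombuffer(json.dumps(meta).encode(), np.uint8)
    )


def load_series(path) -> ImageSeries:
    with np.load(path) as z:
        frames = z["frames"]
        meta = json.loads(bytes(z["meta"]).decode())
    paradigm = None
    if "paradigm" in meta:
        paradigm = Paradigm(*meta["paradigm"])
    return ImageSeries(frames, paradigm=paradigm, provenance=meta["provenance"])
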