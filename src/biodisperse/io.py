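"""File I/O and run configuration.

Stacks travel as multi-page grayscale TIFF (one page per z-slice, page 0 at
the substratum) with a JSON sidecar carrying the voxel sizes in μm
(``{"dx_um": ..., "dy_um": ..., "dz_um": ...}``); tables are UTF-8 CSV with
a mandatory header row and decimal points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .eps_quant import DEFAULT_EXTRACT_VOLUME_ML, DEFAULT_MEMBRANE_AREA_CM2
from .stack_metrics import VoxelStack, binarize

__all__ = ["RunConfig", "read_sidecar", "read_stack", "load_voxel_stack", "write_stack"]

SIDECAR_KEYS = ("dx_um", "dy_um", "dz_um")


@dataclass
class RunConfig:
    """Defaults matching the reference experimental protocol."""

    include_empty: bool = True
    threshold_method: str = "otsu"
    threshold: float | None = None
    ttest_variant: str = "student"
    di_constraint: str = "nonneg"
    di_scaling: str = "raw"
    membrane_area_cm2: float = DEFAULT_MEMBRANE_AREA_CM2
    extract_volume_mL: float = DEFAULT_EXTRACT_VOLUME_ML
    seed: int = 0


def read_sidecar(path) -> tuple[float, float, float]:
    """Voxel sizes (dx, dy, dz) in μm from a JSON sidecar."""
    with open(path) as fh:
        meta = json.load(fh)
    missing = [k for k in SIDECAR_KEYS if k not in meta]
    if missing:
        raise ValueError(f"sidecar {path} missing required keys: {missing} "
                         f"(expected {list(SIDECAR_KEYS)})")
    sizes = tuple(float(meta[k]) for k in SIDECAR_KEYS)
    if any(s <= 0 for s in sizes):
        raise ValueError("sidecar voxel sizes must be positive")
    return sizes


def read_stack(tiff_path, sidecar_path) -> tuple[np.ndarray, float, float, float]:
    """Read a multi-page TIFF as a (z, y, x) array plus voxel sizes."""
    dx, dy, dz = read_sidecar(sidecar_path)
    with tifffile.TiffFile(tiff_path) as tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent page dimensions in {tiff_path}: "
                             f"{sorted(shapes)}")
        arr = tf.asarray()
    if arr.ndim == 2:
        arr = arr[None]
    return arr, dx, dy, dz


def load_voxel_stack(tiff_path, sidecar_path, method: str = "otsu",
                     threshold: float | None = None) -> VoxelStack:
    """Read a stack and binarize it (pre-binarized masks pass through)."""
    arr, dx, dy, dz = read_stack(tiff_path, sidecar_path)
    if arr.dtype == bool or set(np.unique(arr)) <= {0, 1}:
        return VoxelStack(arr.astype(bool), dx=dx, dy=dy, dz=dz)
    return binarize(arr, method=method, threshold=threshold, dx=dx, dy=dy, dz=dz)


def write_stack(tiff_path, sidecar_path, data, dx: float, dy: float, dz: float) -> None:
    """Write a (z, y, x) array as multi-page TIFF plus its JSON sidecar."""
    arr = np.asarray(data)
    if arr.ndim != 3:
        raise ValueError("stack must be 3-D (z, y, x)")
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    tifffile.imwrite(tiff_path, arr)
    Path(sidecar_path).write_text(
        json.dumps({"dx_um": dx, "dy_um": dy, "dz_um": dz}, indent=2))
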