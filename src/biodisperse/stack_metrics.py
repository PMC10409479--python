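"""Structural quantification of biofilm confocal z-stacks.

Implements the four standard COMSTAT-style structure factors computed from a
binarized three-dimensional occupancy grid: total biomass (biovolume per
substratum area), surface-to-biovolume ratio (SBR), mean thickness, and the
roughness coefficient Ra*.  Conventions:

* stacks are indexed ``(z, y, x)`` with ``z = 0`` at the substratum;
* column thickness is the distance from the substratum to the *top* of the
  highest occupied voxel, ignoring interior voids;
* empty columns count as zero-thickness measurements by default, which is the
  convention under which Ra* of a patchy thin film approaches its
  ``2 * (1 - coverage)`` bound;
* for the exposed surface area, faces on the substratum and on the lateral
  stack boundary are not exposed to the bulk liquid, while the open top of
  the stack is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "VoxelStack",
    "ThicknessMap",
    "BiofilmStructure",
    "binarize",
    "biovolume",
    "total_biomass",
    "thickness_map",
    "mean_thickness",
    "roughness_coefficient",
    "surface_area",
    "surface_to_biovolume",
    "quantify_stack",
    "filter_small_components",
]


@dataclass(frozen=True)
class VoxelStack:
    """A binarized biofilm stack with anisotropic voxel sizes in micrometres.

    Parameters
    ----------
    mask
        Boolean occupancy grid of shape ``(nz, ny, nx)``; ``mask[0]`` is the
        slice in contact with the substratum.
    dx, dy, dz
        Voxel edge lengths along x, y and z, in micrometres.
    """

    mask: np.ndarray
    dx: float = 1.0
    dy: float = 1.0
    dz: float = 1.0

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError(f"mask must be 3-D (z, y, x); got ndim={mask.ndim}")
        if min(mask.shape) < 1:
            raise ValueError("every stack dimension must be >= 1")
        for name in ("dx", "dy", "dz"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        return self.dx * self.dy * self.dz

    @property
    def substratum_area(self) -> float:
        """Area of the imaged substratum in μm²."""
        nz, ny, nx = self.mask.shape
        return nx * self.dx * ny * self.dy


@dataclass(frozen=True)
class ThicknessMap:
    """Per-column biofilm thicknesses and the summary entering Ra*.

    ``L`` holds one thickness per (y, x) column in μm (0 for empty columns);
    ``included`` marks the columns counted as measurements under the chosen
    empty-column policy; ``n`` and ``mean`` are the number and mean of the
    included measurements.
    """

    L: np.ndarray
    included: np.ndarray = field(repr=False)
    n: int = 0
    mean: float = 0.0

    def values(self) -> np.ndarray:
        """The included thickness measurements as a flat array."""
        return self.L[self.included]


@dataclass(frozen=True)
class BiofilmStructure:
    """The four structure factors for one stack.

    total_biomass in μm³·μm⁻², sbr in μm²·μm⁻³, mean_thickness in μm,
    roughness dimensionless (Ra*, in [0, 2]).
    """

    total_biomass: float
    sbr: float
    mean_thickness: float
    roughness: float


def binarize(
    intensity: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    *,
    dx: float = 1.0,
    dy: float = 1.0,
    dz: float = 1.0,
) -> VoxelStack:
    """Threshold a grayscale stack into a :class:`VoxelStack`.

    ``method="fixed"`` keeps voxels with intensity strictly above
    ``threshold``; ``method="otsu"`` selects the global Otsu level over the
    whole stack.  Voxel sizes are passed through unchanged.
    """
    arr = np.asarray(intensity)
    if arr.size == 0:
        raise ValueError("empty intensity stack")
    if np.any(arr < 0):
        raise ValueError("negative intensities are not valid image data")
    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        level = float(threshold)
    elif method == "otsu":
        if np.all(arr == arr.flat[0]):
            raise ValueError(
                "no bimodal separation: constant-intensity stack has no Otsu threshold"
            )
        level = float(threshold_otsu(arr))
    else:
        raise ValueError(f"unknown method {method!r}; use 'fixed' or 'otsu'")
    return VoxelStack(arr > level, dx=dx, dy=dy, dz=dz)


def biovolume(vs: VoxelStack) -> float:
    """Total biomass volume: occupied voxels × voxel volume (μm³)."""
    return int(vs.mask.sum()) * vs.voxel_volume


def total_biomass(vs: VoxelStack) -> float:
    """Biovolume per substratum area (μm³·μm⁻²)."""
    return biovolume(vs) / vs.substratum_area


def thickness_map(vs: VoxelStack, include_empty: bool = True) -> ThicknessMap:
    """Per-column thickness: substratum to the top of the highest voxel.

    Interior voids do not reduce a column's thickness.  Empty columns have
    thickness 0 and are counted as measurements when ``include_empty`` is
    true (the default policy used throughout this package).
    """
    mask = vs.mask
    nz = mask.shape[0]
    occupied = mask.any(axis=0)
    # index of topmost occupied layer per column
    top = nz - 1 - np.argmax(mask[::-1], axis=0)
    L = np.where(occupied, (top + 1) * vs.dz, 0.0)
    included = np.ones_like(occupied) if include_empty else occupied
    n = int(included.sum())
    if n == 0:
        raise ValueError("no biomass: no occupied column to measure")
    return ThicknessMap(L=L, included=included, n=n, mean=float(L[included].mean()))


def mean_thickness(tm: ThicknessMap) -> float:
    """Arithmetic mean of the included column thicknesses (μm)."""
    if tm.n < 1:
        raise ValueError("mean thickness undefined: no measurements")
    return tm.mean


def roughness_coefficient(tm: ThicknessMap) -> float:
    """Roughness coefficient Ra* = mean(|L_i − L̄|) / L̄.

    Dimensionless measure of thickness variability: 0 for a uniform film and
    at most 2 for any nonnegative thickness distribution.
    """
    vals = tm.values()
    m = tm.mean
    if m <= 0:
        raise ValueError("roughness undefined for empty biofilm (mean thickness 0)")
    return float(np.abs(vals - m).mean() / m)


def surface_area(vs: VoxelStack) -> float:
    """Biofilm area exposed to the bulk liquid (μm²).

    Counts occupied-voxel faces adjacent to an unoccupied voxel, plus top
    faces at the open upper boundary.  Substratum-contact faces and faces on
    the lateral boundary of the imaged volume are not exposed.
    """
    m = vs.mask
    ax = vs.dy * vs.dz  # x-normal face area
    ay = vs.dx * vs.dz
    az = vs.dx * vs.dy
    # internal faces: occupied next to unoccupied, both directions
    fx = np.count_nonzero(m[:, :, 1:] ^ m[:, :, :-1])
    fy = np.count_nonzero(m[:, 1:, :] ^ m[:, :-1, :])
    fz = np.count_nonzero(m[1:, :, :] ^ m[:-1, :, :])
    # open top: occupied voxels in the last slice expose their top face
    fz += np.count_nonzero(m[-1])
    return fx * ax + fy * ay + fz * az


def surface_to_biovolume(vs: VoxelStack) -> float:
    """Exposed surface area divided by biovolume (μm²·μm⁻³)."""
    bv = biovolume(vs)
    if bv <= 0:
        raise ValueError("SBR undefined: zero biomass")
    return surface_area(vs) / bv


def filter_small_components(vs: VoxelStack, min_volume_um3: float) -> VoxelStack:
    """Remove 6-connected components smaller than ``min_volume_um3``.

    Optional pre-filter; quantification applies no connectivity filtering by
    default.
    """
    labels, nlab = ndimage.label(vs.mask)
    if nlab == 0:
        return vs
    counts = np.bincount(labels.ravel())
    keep = counts * vs.voxel_volume >= min_volume_um3
    keep[0] = False
    return VoxelStack(keep[labels], dx=vs.dx, dy=vs.dy, dz=vs.dz)


def quantify_stack(vs: VoxelStack, include_empty: bool = True) -> BiofilmStructure:
    """Compute all four structure factors under one empty-column policy."""
    if biovolume(vs) <= 0:
        raise ValueError("cannot quantify an empty stack")
    tm = thickness_map(vs, include_empty=include_empty)
    return BiofilmStructure(
        total_biomass=total_biomass(vs),
        sbr=surface_to_biovolume(vs),
        mean_thickness=mean_thickness(tm),
        roughness=roughness_coefficient(tm),
    )
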