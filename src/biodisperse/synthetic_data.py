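"""Synthetic biofilm stacks and dose–response datasets.

Dispersing biofilms thin out, fragment into patches, and hollow into
shell-like structures with walls of cells around empty centers.  The stack
generator emulates this with three ingredients driven by a single dispersion
level ``d`` in [0, 1]:

* a smooth random height field, scaled by ``(1 − d) · base_thickness`` and
  with relative relief growing with ``d`` (thinner, rougher films);
* clustered column removal down to a ``d``-reduced coverage (patchiness);
* random removal of interior voxels below each column's top with
  probability ``0.85·d`` (hollow shells; the top voxel is kept, so the
  thickness map is unchanged while SBR rises).

The dose-series generator maps dose to ``d = dose / max(dose)`` and
interpolates OD600, protein and polysaccharide between the control and
top-dose anchor values of two strain presets (a P. aeruginosa PAO1 pure
culture and a six-strain membrane-bioreactor consortium).  Anchors are the
control/top-dose levels measured in the reference dose–response experiment
bundled with the package, so the generated trends have the directions the
analysis assumes: OD up with dose; EPS, biomass and thickness down; SBR and
roughness up; protein declining proportionally faster than polysaccharide.
Noise is multiplicative log-normal (all quantities are positive).

Every output is a pure function of (recipe, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .stack_metrics import VoxelStack, quantify_stack

__all__ = [
    "StackRecipe",
    "DoseRecipe",
    "generate_stack",
    "generate_dose_series",
    "DoseSeriesDataset",
    "ReferenceDataset",
    "reference_dataset",
    "STRAIN_PRESETS",
]

#: Anchor values per strain preset: control (d = 0) and top dose (d = 1).
STRAIN_PRESETS = {
    "pao1": dict(od=(0.357, 0.490), protein=(2.75, 0.46),
                 polysaccharide=(3.61, 1.42), base_thickness=39.0),
    "multi": dict(od=(0.292, 0.490), protein=(3.44, 0.65),
                  polysaccharide=(4.90, 3.81), base_thickness=43.9),
}

HOLLOW_PROB_SCALE = 0.85   # interior-removal probability at d = 1
COVERAGE_LOSS = 0.85       # fraction of columns lost at d = 1
RELIEF_GAIN = 1.2          # extra relative relief of the height field at d = 1


@dataclass(frozen=True)
class StackRecipe:
    """Parameters of one synthetic stack; identical recipe + seed ⇒ identical stack."""

    nx: int = 64
    ny: int = 64
    nz: int = 48
    dx: float = 1.0
    dy: float = 1.0
    dz: float = 1.0
    coverage: float = 1.0
    base_thickness: float = 39.0
    dispersion: float = 0.0
    relief: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("grid dimensions must be >= 1")
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel sizes must be positive")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")
        if not 0 <= self.dispersion <= 1:
            raise ValueError("dispersion must be in [0, 1]")
        if not 0 < self.base_thickness <= self.nz * self.dz:
            raise ValueError("base_thickness must be in (0, nz*dz]")
        if self.relief < 0:
            raise ValueError("relief must be nonnegative")


def _smooth_field(rng: np.random.Generator, ny: int, nx: int) -> np.ndarray:
    """Standardized low-frequency random field on the (y, x) grid."""
    sigma = max(2.0, min(ny, nx) / 8.0)
    g = gaussian_filter(rng.standard_normal((ny, nx)), sigma=sigma, mode="wrap")
    sd = g.std()
    return (g - g.mean()) / sd if sd > 0 else np.zeros_like(g)


def generate_stack(recipe: StackRecipe) -> VoxelStack:
    """Build one synthetic biofilm stack from a recipe."""
    r = recipe
    rng = np.random.default_rng(r.seed)
    d = r.dispersion

    # height field: thinner and relatively rougher as dispersion grows
    relief = r.relief + RELIEF_GAIN * d
    heights = r.base_thickness * (1.0 - d) * (1.0 + relief * _smooth_field(rng, r.ny, r.nx))
    heights = np.clip(heights, r.dz, r.nz * r.dz)

    # patchiness: keep the top-ranked columns of a ranking field that is
    # smooth at low dispersion (contiguous patches) and white at high
    # dispersion (scattered pillars and shell walls, high exposed area)
    cov_eff = r.coverage * (1.0 - COVERAGE_LOSS * d)
    n_cols = r.ny * r.nx
    n_keep = max(1, int(round(cov_eff * n_cols)))
    rank_field = ((1.0 - d) * _smooth_field(rng, r.ny, r.nx)
                  + (d + 1e-9) * rng.standard_normal((r.ny, r.nx)))
    keep = np.zeros(n_cols, dtype=bool)
    keep[np.argsort(rank_field.ravel())[::-1][:n_keep]] = True
    keep = keep.reshape(r.ny, r.nx)

    n_layers = np.where(keep, np.ceil(heights / r.dz).astype(int), 0)
    z = np.arange(r.nz)[:, None, None]
    mask = z < n_layers[None, :, :]

    # hollow shells: drop interior voxels below each column top
    if d > 0:
        interior = z < (n_layers[None, :, :] - 1)
        drop = interior & (rng.random(mask.shape) < HOLLOW_PROB_SCALE * d)
        mask = mask & ~drop

    return VoxelStack(mask, dx=r.dx, dy=r.dy, dz=r.dz)


@dataclass(frozen=True)
class DoseRecipe:
    """Parameters of a synthetic dose–response experiment."""

    doses: tuple = (0.0, 100.0, 200.0, 300.0)
    strain_preset: str = "pao1"
    noise_sd: float = 0.05
    n_replicates: int = 3
    seed: int = 0
    nx: int = 48
    ny: int = 48
    nz: int = 48
    dz: float = 1.0

    def __post_init__(self) -> None:
        doses = tuple(float(x) for x in self.doses)
        if len(doses) == 0:
            raise ValueError("empty dose list")
        if any(x < 0 for x in doses):
            raise ValueError("doses must be nonnegative")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if self.strain_preset not in STRAIN_PRESETS:
            raise ValueError(f"unknown preset {self.strain_preset!r}; "
                             f"choose from {sorted(STRAIN_PRESETS)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        object.__setattr__(self, "doses", doses)


@dataclass(frozen=True)
class DoseSeriesDataset:
    """Generated dose-series tables, one row set per dose level."""

    od: pd.DataFrame
    eps: pd.DataFrame
    structure: pd.DataFrame

    def components(self) -> pd.DataFrame:
        """Join mean OD, SBR, roughness and EPS total per dose for DI fitting."""
        od_mean = (self.od.groupby(["strain", "dose_nM"], as_index=False)["od600"]
                   .mean())
        out = od_mean.merge(self.structure[["strain", "dose_nM", "sbr_um2_um3",
                                            "roughness"]], on=["strain", "dose_nM"])
        out = out.merge(self.eps[["strain", "dose_nM", "eps_total_ug_cm2"]],
                        on=["strain", "dose_nM"])
        return out.rename(columns={"od600": "od600_mean"})


def _noisy(rng: np.random.Generator, value: float, sd: float, size=None):
    """Mean-preserving multiplicative log-normal noise."""
    if sd == 0:
        return value if size is None else np.full(size, value)
    return value * rng.lognormal(-0.5 * sd**2, sd, size=size)


def generate_dose_series(recipe: DoseRecipe) -> DoseSeriesDataset:
    """Generate OD replicates, EPS components and structure metrics per dose."""
    r = recipe
    preset = STRAIN_PRESETS[r.strain_preset]
    rng = np.random.default_rng(r.seed)
    stack_seeds = np.random.SeedSequence(r.seed).spawn(len(r.doses))
    dmax = max(r.doses)

    od_rows, eps_rows, struct_rows = [], [], []
    base = min(preset["base_thickness"], r.nz * r.dz)
    for i, dose in enumerate(r.doses):
        d = dose / dmax if dmax > 0 else 0.0

        def lerp(pair):
            return pair[0] + (pair[1] - pair[0]) * d

        for rep in range(r.n_replicates):
            od_rows.append(dict(strain=r.strain_preset, dose_nM=dose, replicate=rep,
                                od600=float(_noisy(rng, lerp(preset["od"]), r.noise_sd))))
        prot = float(_noisy(rng, lerp(preset["protein"]), r.noise_sd))
        poly = float(_noisy(rng, lerp(preset["polysaccharide"]), r.noise_sd))
        eps_rows.append(dict(strain=r.strain_preset, dose_nM=dose,
                             protein_ugBSA_cm2=prot, polysaccharide_ugC_cm2=poly,
                             eps_total_ug_cm2=prot + poly))

        stack = generate_stack(StackRecipe(
            nx=r.nx, ny=r.ny, nz=r.nz, dz=r.dz, base_thickness=base,
            dispersion=d, seed=int(stack_seeds[i].generate_state(1)[0] % 2**31)))
        s = quantify_stack(stack)
        struct_rows.append(dict(strain=r.strain_preset, dose_nM=dose,
                                total_biomass_um3_um2=s.total_biomass,
                                sbr_um2_um3=s.sbr, mean_thickness_um=s.mean_thickness,
                                roughness=s.roughness))

    return DoseSeriesDataset(od=pd.DataFrame(od_rows), eps=pd.DataFrame(eps_rows),
                             structure=pd.DataFrame(struct_rows))


@dataclass(frozen=True)
class ReferenceDataset:
    """The published dose–response measurements bundled with the package.

    ``od`` has NaN mean/sd where a dose level was never reported numerically
    (PAO1 at 100 and 200 nM); downstream fits use only complete rows.
    """

    od: pd.DataFrame
    eps: pd.DataFrame
    structure: pd.DataFrame

    def missing_od(self) -> pd.DataFrame:
        """Dose levels whose OD summary is unreported."""
        return self.od[self.od["od_mean"].isna()][["strain", "dose_nM"]]

    def di_components(self) -> pd.DataFrame:
        """The complete (OD, SBR, roughness, EPS) tuples for DI fitting.

        EPS totals are the canonical component sums.  Only rows with a
        reported OD mean are returned (six of the eight conditions).
        """
        eps = self.eps.copy()
        eps["eps_total_ug_cm2"] = (eps["protein_ugBSA_cm2"]
                                   + eps["polysaccharide_ugC_cm2"])
        out = (self.od.dropna(subset=["od_mean"])
               .merge(self.structure[["strain", "dose_nM", "sbr_um2_um3", "roughness"]],
                      on=["strain", "dose_nM"])
               .merge(eps[["strain", "dose_nM", "eps_total_ug_cm2"]],
                      on=["strain", "dose_nM"]))
        return out.rename(columns={"od_mean": "od600_mean"})


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("biodisperse.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def reference_dataset() -> ReferenceDataset:
    """Load the bundled reference measurements (OD, EPS, structure tables)."""
    return ReferenceDataset(od=_load_csv("reference_od.csv"),
                            eps=_load_csv("reference_eps.csv"),
                            structure=_load_csv("reference_structure.csv"))
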