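# biodisperse

Quantitative analysis of signal-induced biofilm dispersion for membrane
biofouling studies.

Fatty-acid quorum-sensing signals of the diffusible-signal-factor family,
such as *cis*-2-decenoic acid (CDA), trigger biofilm dispersion: cells leave
the film for the bulk liquid, the extracellular polymeric substance (EPS)
matrix shrinks, and the residual film becomes thin, patchy and shell-like.
`biodisperse` turns the standard readouts of such experiments — confocal
z-stacks of the film, OD600 of the released cells, and protein/polysaccharide
assays of the EPS — into comparable numbers, and condenses them into a single
**Dispersion Index (DI)**.

## What it computes

**Stack structure factors** (COMSTAT-style), from a binarized confocal stack
with voxel sizes (dx, dy, dz) in μm:

- total biomass `= biovolume / substratum area` (μm³·μm⁻²),
- surface-to-biovolume ratio `SBR = exposed area / biovolume` (μm²·μm⁻³),
- mean thickness `L̄` over per-column heights (μm), and
- roughness coefficient `Ra* = (1/N) Σ |L_i − L̄| / L̄ ∈ [0, 2]`.

**EPS composition**: Bradford standard-curve regression and inversion, areal
normalization (μg/cm²), `EPS = protein + polysaccharide`, composition
fractions and percent changes versus the untreated control.

**Dispersal statistics**: replicate OD600 summaries, pooled or Welch
two-sample t-tests of dose versus control, and the linear dose trend.

**Dispersion Index**: the weighted average

```
DI = (r_o·OD + r_s·SBR + r_r·Ra*) / (r_o + r_s + r_r)
```

with relevance weights fitted to maximize the R² of the linear DI–EPS
relationship. Because R² of a one-dimensional regression on a linear
combination is the squared Pearson correlation, the unconstrained optimum
equals the multiple-regression R² of EPS on (OD, SBR, Ra*); the default
nonnegative-weight fit is solved exactly by face enumeration. The fitted
DI–EPS slope is negative — dispersed films carry little EPS — so high DI
reads as "strongly dispersed".

A synthetic-data module generates voxel stacks (smooth height fields that
thin, fragment and hollow into shells as a dispersion level `d ∈ [0, 1]`
rises) and full dose–response datasets, so the entire pipeline is testable
with no experimental data. A reference dataset of published CDA
dose–response measurements for *Pseudomonas aeruginosa* PAO1 and a
six-strain membrane-bioreactor consortium is bundled as plain CSV.

## Worked example

```python
from biodisperse import (StackRecipe, generate_stack, quantify_stack,
                         reference_dataset, fit_weights)

# a synthetic dispersing biofilm (60% dispersion level)
vs = generate_stack(StackRecipe(nx=64, ny=64, nz=48,
                                base_thickness=39.0, dispersion=0.6, seed=7))
s = quantify_stack(vs)
print(f"biomass={s.total_biomass:.3f} sbr={s.sbr:.3f} "
      f"thick={s.mean_thickness:.3f} rough={s.roughness:.3f}")

# DI weights fitted on the bundled reference measurements
comp = reference_dataset().di_components()
res = fit_weights(comp[["od600_mean", "sbr_um2_um3", "roughness"]].to_numpy(),
                  comp["eps_total_ug_cm2"].to_numpy())
print(res.weights, f"r2={res.r2_eps:.4f} slope={res.slope:.2f}")
```

prints

```
biomass=4.110 sbr=3.867 thick=7.909 rough=1.267
DIWeights(ro=0.9453..., rs=0.0, rr=0.0547...) r2=0.9649 slope=-20.64
```

The synthetic film at `d = 0.6` has already lost most of its biomass
(4.1 μm³·μm⁻² versus ~39 for the undisturbed film) while SBR and roughness
have climbed — the signature of dispersion. On the six complete reference
tuples the fitted weights put most relevance on OD with a roughness
contribution and none on SBR; the DI–EPS line explains 96.5% of the EPS
variance with the expected negative slope.

A command-line interface mirrors the library:

```sh
biodisperse simulate stack --dispersion 0.6 --seed 7 --out film.tiff --sidecar film.json
biodisperse quantify film.tiff --sidecar film.json
biodisperse eps table.csv        # strain,dose_nM,polysaccharide_ugC_cm2,protein_ugBSA_cm2
biodisperse dispersal od.csv     # strain,dose_nM,replicate,od600
biodisperse di-fit components.csv --constraint nonneg
biodisperse report --json        # recompute the bundled reference statistics
```

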