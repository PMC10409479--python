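# Methods

## Stack metrics

A biofilm stack is a boolean occupancy grid indexed `(z, y, x)` with `z = 0`
at the substratum and per-axis voxel sizes in μm (anisotropic voxels are
supported; `dz` commonly differs from `dx = dy`). Grayscale stacks are
binarized by a global Otsu threshold by default, with a fixed-threshold
override; pre-binarized masks pass through. No connectivity filtering is
applied by default (an optional minimum-component-volume filter exists),
since the structure factors are defined on the raw occupancy field.

Conventions chosen where the quantities themselves leave room:

- **Thickness** of a column is the distance from the substratum to the *top*
  of its highest occupied voxel; interior voids are ignored. This makes
  thickness invariant under hollowing, which is what "film height" means for
  a shell-like dispersing biofilm.
- **Empty-column policy**: zero-thickness columns count as measurements
  (`include_empty=True` default). Under this policy the roughness
  coefficient `Ra* = mean(|L_i − L̄|)/L̄` of a binary-height film approaches
  its analytic bound `2·(1 − coverage)`; observed values near 2 in sparse
  films are only attainable this way. `Ra*` is provably ≤ 2 for any
  nonnegative thickness field, since `Σ|L_i − m| = 2·Σ_{L_i>m}(L_i − m) ≤
  2·Σ L_i = 2Nm`.
- **Exposed surface area** counts occupied-voxel faces adjacent to an
  unoccupied voxel, plus top faces at the open upper boundary. Faces on the
  substratum and on the lateral boundary of the imaged volume are treated as
  unexposed: SBR is meant to read "area available to nutrient flow", and
  this convention gives the solid slab the closed form `SBR = 1/(nz·dz)`.

Degenerate inputs raise: roughness and SBR are undefined on an empty stack,
Otsu on a constant stack has no bimodal separation.

## EPS quantification

EPS is the sum of protein and polysaccharide, each normalized to the
membrane specimen area. Protein comes from a Bradford assay: an OLS standard
curve `A595 = slope·c + intercept` on BSA dilutions, inverted per sample;
absorbances below the intercept back-calculate negative and are clipped to 0
with a warning (blank-level noise is expected, not an error). Polysaccharide
is accepted directly as areal organic carbon (μg C/cm²) with no instrument
model and no conversion to glucose equivalents. Defaults follow the
reference protocol: 15 mL extract over a 1.5 cm × 1.5 cm (2.25 cm²)
specimen, both overridable. Where a table carries printed EPS totals, the
component sum is canonical and printed totals within 0.02 μg/cm² are treated
as rounding.

## Dispersal statistics

Replicate OD600 readings are summarized as mean ± sample sd (n−1
denominator; sd is reported as undefined for n = 1, never 0). The default
dose-versus-control test is the two-tailed pooled-variance Student t
(df = n1+n2−2), the variant implied by common spreadsheet analyses of such
assays; Welch is available by flag. No multiple-testing correction is
applied by default; Holm adjustment is behind a flag. When both groups have
zero spread and equal means, t = 0 and p = 1 by convention.

## Dispersion Index

DI is the weighted average of OD, SBR and roughness with nonnegative
relevance weights, reported in canonical sum-to-1 form (DI is invariant
under positive rescaling of the weights). Weights are fitted by maximizing
the R² of a simple linear regression between DI and EPS, where R² is defined
as the squared Pearson correlation (equal to the OLS R² with intercept; the
definition is stated because composite-index practice varies).

The optimizer is exact, not iterative. The squared correlation of `X·w` with
`y` is invariant under affine maps of `X·w`, so its unconstrained maximum
over directions `w` is the multiple-regression R² of `y` on the columns of
`X`, attained at the OLS coefficient direction. For the nonnegative
constraint, a direction is feasible iff its coefficients share one sign
(either sign scales into the nonnegative orthant); if the full OLS direction
is infeasible the optimum lies on a face of the constraint set with some
weights pinned to zero, and for three components enumerating every nonempty
component subset is exhaustive. Ties between faces prefer fewer zero
weights. Rank-deficient component matrices (all rows identical) and constant
EPS raise with a diagnostic; at least 4 observations are required.

Components enter on their raw scales by default — the weights absorb the
units, and no normalization is assumed of the index definition — with
min-max scaling available for cross-dataset comparisons (it reparametrizes
the same combination space and leaves the achieved R² unchanged).

The estimator (`DispersionIndexRegressor`) follows scikit-learn conventions:
`fit(X, y)` with `X = (od, sbr, roughness)` and `y = eps`, `transform`
returning DI, `predict` returning EPS through the fitted DI–EPS line, fitted
attributes `weights_`, `di_`, `r2_`, `slope_`, `intercept_`.

On the bundled reference tuples only six of eight (strain, dose) conditions
have a complete (OD, SBR, roughness, EPS) record — the PAO1 OD summaries at
100 and 200 nM were never reported numerically — so the DI fit runs on those
six, and the per-strain DI-versus-dose regression is evaluated only for the
multi-strain series (the one strain with ≥ 3 complete dose levels). The
published p-values for the dispersal assay depend on an unstated comparison
grouping and are not recomputed; the t-test is instead validated against its
closed form.

## Synthetic data

The stack generator emulates the morphology of a dispersing film with a
single dispersion level `d ∈ [0, 1]`:

- column heights follow a low-frequency (Gaussian-smoothed, standardized)
  random field scaled by `(1 − d)·base_thickness`, with relative relief
  `relief + 1.2·d` (default `relief = 0.15`), floored at one voxel layer so
  the film at `d = 1` is a thin patchy monolayer rather than vanishing;
- occupied columns are the top-ranked fraction `coverage·(1 − 0.85·d)` of a
  ranking field that blends smooth (contiguous patches at low `d`) into
  white noise (scattered pillars and shell walls at high `d`);
- interior voxels strictly below each column top are removed with
  probability `0.85·d`, producing hollow shells: thickness is unchanged
  while exposed area and SBR rise.

This is deliberately phenomenological — a height-field model, not a growth
simulation. It spans the observed metric space (biomass falling ~99%, SBR
rising several-fold, roughness approaching 2 across a dose series) and gives
the analysis stages monotone trends to recover, but it does not model
optics (PSF, attenuation with depth), cell-scale granularity, or any
biophysics of dispersion; passing tests demonstrate the pipeline's
arithmetic and trend recovery, not realism of any particular biofilm.
`coverage` is the occupied-column target at `d = 0`; recovery is within
±0.05 of the `d`-adjusted target by construction of the rank-order
selection.

The dose-series generator maps dose to `d = dose/max(dose)` and linearly
interpolates OD, protein and polysaccharide between control and top-dose
anchors taken from the bundled reference measurements (PAO1:
OD 0.357→0.490, protein 2.75→0.46, polysaccharide 3.61→1.42 μg/cm²,
39 μm base thickness; consortium: 0.292→0.490, 3.44→0.65, 4.90→3.81,
43.9 μm). Protein therefore declines proportionally faster than
polysaccharide, as observed. Noise is mean-preserving multiplicative
log-normal (sd 0.05 by default, three OD replicates) — additive Gaussian was
rejected because all quantities are positive. Structure metrics per dose
come from an actual generated stack (48×48×48 voxels by default, chosen to
keep a full series cheap while leaving ≥ 40 layers below the top), so they
carry generator randomness even at zero table noise.

## Problem sizes in tests and the acceptance script

Brute-force oracle comparisons run on random stacks up to 32×32×16 voxels
(100 stacks), where triple-loop reference implementations are exact and
fast. The weight-fit oracle check covers 50 random datasets of 8–30
observations. Synthetic trend checks average 10 seeds per dispersion level;
the pipeline-recovery statistic in the acceptance script averages 20
generated dose series at noise sd 0.05. All table-derived statistics are
desk-scale arithmetic on the bundled 8-row tables.

## Known limitations

- The reference structure factors were produced by proprietary imaging
  software whose threshold and connectivity settings are unknown; the
  bundled structure table is treated as given data, and this package's stack
  metrics are validated against brute-force oracles and closed forms rather
  than against that table.
- DI weights carry no uncertainty intervals; with six observations and
  three components the fit is descriptive, not inferential.
- The component set is fixed at (OD, SBR, roughness); the index is not
  generalized to arbitrary column sets.
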