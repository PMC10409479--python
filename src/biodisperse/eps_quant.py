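"""Extracellular polymeric substance (EPS) quantification arithmetic.

EPS of a membrane biofilm is defined as the sum of its protein and
polysaccharide contents, each normalized to the membrane specimen area.
Proteins come from a Bradford assay (A595 against a BSA standard curve);
polysaccharide is measured directly as areal organic carbon and accepted as
a concentration input.  This module holds the standard-curve regression, the
absorbance-to-concentration inversion, areal normalization, composition
fractions and percent-change statistics used to summarize dose responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "EPSRecord",
    "fit_standard_curve",
    "protein_concentration",
    "areal_mass",
    "eps_total",
    "protein_fraction",
    "polysaccharide_fraction",
    "percent_change",
    "summarize_eps_table",
    "DEFAULT_MEMBRANE_AREA_CM2",
    "DEFAULT_EXTRACT_VOLUME_ML",
]

#: Membrane specimen area: a 1.5 cm × 1.5 cm coupon piece.
DEFAULT_MEMBRANE_AREA_CM2 = 2.25
#: Extraction volume of 0.9% NaCl per specimen, in mL.
DEFAULT_EXTRACT_VOLUME_ML = 15.0


@dataclass(frozen=True)
class StandardCurve:
    """Linear Bradford calibration: absorbance = slope·(μg/mL) + intercept."""

    slope: float
    intercept: float
    r2: float = 1.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("standard curve slope must be positive")
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError("r2 must lie in [0, 1]")


@dataclass(frozen=True)
class EPSRecord:
    """One dose-level EPS measurement (areal concentrations in μg/cm²)."""

    strain: str
    dose: float
    polysaccharide: float
    protein: float

    def __post_init__(self) -> None:
        if self.polysaccharide < 0 or self.protein < 0:
            raise ValueError("concentrations must be nonnegative")

    @property
    def eps_total(self) -> float:
        return eps_total(self.protein, self.polysaccharide)


def fit_standard_curve(points) -> StandardCurve:
    """Ordinary least squares of absorbance on BSA concentration.

    ``points`` is a sequence of ``(concentration_ug_per_mL, absorbance)``
    pairs; at least three points over at least two distinct concentrations.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (concentration, absorbance) points")
    conc, absb = pts[:, 0], pts[:, 1]
    if np.ptp(conc) == 0:
        raise ValueError("degenerate design: all concentrations identical")
    fit = stats.linregress(conc, absb)
    return StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                         r2=float(fit.rvalue**2))


def protein_concentration(a595: float, curve: StandardCurve) -> float:
    """Invert the standard curve: (A595 − intercept) / slope, in μg/mL.

    Absorbances below the intercept (blank-level noise) back-calculate to a
    negative concentration; these are clipped to 0 with a warning.
    """
    c = (a595 - curve.intercept) / curve.slope
    if c < 0:
        warnings.warn(
            f"absorbance {a595} below curve intercept {curve.intercept}; "
            "clipping concentration to 0",
            stacklevel=2,
        )
        return 0.0
    return float(c)


def areal_mass(concentration: float, extract_volume_mL: float = DEFAULT_EXTRACT_VOLUME_ML,
               membrane_area_cm2: float = DEFAULT_MEMBRANE_AREA_CM2) -> float:
    """Convert an extract concentration (μg/mL) to areal mass (μg/cm²)."""
    if extract_volume_mL <= 0:
        raise ValueError("extract volume must be positive")
    if membrane_area_cm2 <= 0:
        raise ValueError("membrane area must be positive")
    return concentration * extract_volume_mL / membrane_area_cm2


def eps_total(protein: float, polysaccharide: float) -> float:
    """EPS = protein + polysaccharide, both in μg/cm²."""
    if protein < 0 or polysaccharide < 0:
        raise ValueError("concentrations must be nonnegative")
    return protein + polysaccharide


def protein_fraction(protein: float, polysaccharide: float) -> float:
    """Protein share of total EPS, in percent."""
    tot = eps_total(protein, polysaccharide)
    if tot <= 0:
        raise ValueError("protein fraction undefined: zero total EPS")
    return 100.0 * protein / tot


def polysaccharide_fraction(protein: float, polysaccharide: float) -> float:
    """Polysaccharide share of total EPS, in percent (100 − protein share)."""
    return 100.0 - protein_fraction(protein, polysaccharide)


def percent_change(v0: float, vd: float) -> float:
    """Percent reduction from a control value: 100·(v0 − vd)/v0.

    Negative when the dosed value exceeds the control.
    """
    if v0 <= 0:
        raise ValueError("percent change undefined for nonpositive control value")
    return 100.0 * (v0 - vd) / v0


def summarize_eps_table(df, control_dose: float = 0.0):
    """Per-record EPS totals, composition fractions and reductions vs control.

    ``df`` needs columns ``strain``, ``dose_nM``, ``polysaccharide_ugC_cm2``
    and ``protein_ugBSA_cm2``.  Returns a copy with ``eps_total_ug_cm2``,
    ``protein_fraction_pct``, ``polysaccharide_fraction_pct`` and, for each
    quantity, ``pct_reduction_vs_0nM`` computed within strain against the
    control dose.  The component sum is canonical for the total.
    """
    import pandas as pd

    required = {"strain", "dose_nM", "polysaccharide_ugC_cm2", "protein_ugBSA_cm2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = df.copy()
    out["eps_total_ug_cm2"] = out["protein_ugBSA_cm2"] + out["polysaccharide_ugC_cm2"]
    out["protein_fraction_pct"] = [
        protein_fraction(p, s)
        for p, s in zip(out["protein_ugBSA_cm2"], out["polysaccharide_ugC_cm2"])
    ]
    out["polysaccharide_fraction_pct"] = 100.0 - out["protein_fraction_pct"]

    reductions = {}
    for col, name in [
        ("eps_total_ug_cm2", "eps_pct_reduction_vs_0nM"),
        ("protein_ugBSA_cm2", "protein_pct_reduction_vs_0nM"),
        ("polysaccharide_ugC_cm2", "polysaccharide_pct_reduction_vs_0nM"),
    ]:
        vals = []
        for _, row in out.iterrows():
            ctrl = out[(out["strain"] == row["strain"]) & (out["dose_nM"] == control_dose)]
            if ctrl.empty:
                vals.append(float("nan"))
            else:
                vals.append(percent_change(float(ctrl[col].iloc[0]), float(row[col])))
        reductions[name] = vals
    return out.assign(**pd.DataFrame(reductions, index=out.index))
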