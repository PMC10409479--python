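"""The Dispersion Index (DI): a composite measure of biofilm dispersion.

DI condenses three complementary readouts of a dispersing biofilm — the
OD600 of released cells, the surface-to-biovolume ratio (SBR) and the
roughness coefficient — into a single weighted average,

    DI = (r_o·OD + r_s·SBR + r_r·Ra*) / (r_o + r_s + r_r),

where the relevance weights (r_o, r_s, r_r) are chosen to maximize the R²
of a simple linear regression between DI and the biofilm's EPS content.
A dispersive biofilm carries little EPS, so the fitted DI–EPS line has
negative slope: high DI means a stripped, dispersed film.

R² here is the squared Pearson correlation between DI and EPS (identical to
the OLS R² with intercept).  Because that correlation is invariant under
affine maps of the linear combination, the unconstrained maximum over weight
directions equals the multiple-regression R² of EPS on (OD, SBR, Ra*) — the
closed form used both by the solver and as the independent oracle in the
tests.  With weights constrained to be nonnegative (their default reading
as "relevance" factors), the optimum either uses the unconstrained
direction, when it can be scaled into the nonnegative orthant, or lies on a
face of the constraint set; for three components an exhaustive face
enumeration is exact.

:class:`DispersionIndexRegressor` exposes the fit in scikit-learn estimator
form; :func:`fit_weights`, :func:`compute_di` and :func:`evaluate_dose_fit`
are thin functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "COMPONENT_NAMES",
    "DIWeights",
    "DIFitResult",
    "DispersionIndexRegressor",
    "compute_di",
    "fit_weights",
    "evaluate_dose_fit",
]

COMPONENT_NAMES = ("od", "sbr", "roughness")


@dataclass(frozen=True)
class DIWeights:
    """Relevance weights (r_o, r_s, r_r), canonically normalized to sum 1.

    DI is invariant under positive rescaling of all three weights, so only
    the direction matters; the canonical form fixes the scale.
    """

    ro: float
    rs: float
    rr: float

    def __post_init__(self) -> None:
        total = self.ro + self.rs + self.rr
        if not total > 0:
            raise ValueError("weight sum must be positive")

    def normalized(self) -> "DIWeights":
        total = self.ro + self.rs + self.rr
        return DIWeights(self.ro / total, self.rs / total, self.rr / total)

    def as_array(self) -> np.ndarray:
        return np.array([self.ro, self.rs, self.rr], dtype=float)


@dataclass(frozen=True)
class DIFitResult:
    """Outcome of a DI weight fit."""

    weights: DIWeights
    di_values: np.ndarray = field(repr=False)
    r2_eps: float = 0.0
    slope: float = 0.0
    intercept: float = 0.0
    r2_dose_by_strain: dict = field(default_factory=dict)


def compute_di(components, weights: DIWeights) -> np.ndarray | float:
    """Weighted average of (OD, SBR, roughness) under the given weights.

    ``components`` is a length-3 sequence or an (n, 3) array in the order
    ``(od, sbr, roughness)``.  The result always lies between the smallest
    and largest of the three components.
    """
    w = weights.as_array()
    total = w.sum()
    if not total > 0:
        raise ValueError("weight sum must be positive")
    arr = np.asarray(components, dtype=float)
    scalar = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 3:
        raise ValueError("components must have 3 columns (od, sbr, roughness)")
    di = arr @ w / total
    return float(di[0]) if scalar else di


def _r2_with_intercept(x: np.ndarray, y: np.ndarray):
    """(R², slope, intercept) of the OLS line y = a + b·x."""
    if np.ptp(x) == 0:
        return 0.0, 0.0, float(y.mean())
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2), float(fit.slope), float(fit.intercept)


def _subset_ols(X: np.ndarray, y: np.ndarray, idx):
    """Multiple-regression R² of y on X[:, idx] with intercept, plus coefs."""
    A = np.column_stack([X[:, list(idx)], np.ones(len(y))])
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot
    return r2, beta[:-1]


class DispersionIndexRegressor(RegressorMixin, BaseEstimator):
    """Fit DI relevance weights by maximizing the DI–EPS R².

    Parameters
    ----------
    constraint : {"nonneg", "unconstrained"}, default "nonneg"
        "nonneg" restricts the weights to the nonnegative orthant (their
        natural reading as relevance factors); "unconstrained" allows any
        direction and attains the multiple-regression R².
    scaling : {"raw", "minmax"}, default "raw"
        "raw" weights the components on their native scales (the weights
        absorb the units); "minmax" rescales each component to [0, 1] on the
        training data first, for cross-dataset comparability.

    Attributes
    ----------
    weights_ : DIWeights
        Fitted relevance weights in canonical sum-to-1 form.
    di_ : ndarray
        DI value of each training observation.
    r2_ : float
        Maximized R² of the DI–EPS simple linear regression.
    slope_, intercept_ : float
        The fitted linear map EPS ≈ intercept + slope·DI (slope is negative
        on dispersing biofilms).
    """

    def __init__(self, constraint: str = "nonneg", scaling: str = "raw"):
        self.constraint = constraint
        self.scaling = scaling

    def _transform_components(self, X: np.ndarray) -> np.ndarray:
        if self.scaling == "raw":
            return X
        span = self.scale_max_ - self.scale_min_
        span = np.where(span > 0, span, 1.0)
        return (X - self.scale_min_) / span

    def fit(self, X, y):
        """Fit weights on components X = (od, sbr, roughness) and EPS y."""
        if self.constraint not in ("nonneg", "unconstrained"):
            raise ValueError(f"unknown constraint {self.constraint!r}")
        if self.scaling not in ("raw", "minmax"):
            raise ValueError(f"unknown scaling {self.scaling!r}")
        X, y = check_X_y(X, y, ensure_min_samples=4, ensure_min_features=3)
        if X.shape[1] != 3:
            raise ValueError("X must have exactly 3 columns (od, sbr, roughness)")
        if np.ptp(y) == 0:
            raise ValueError("EPS response is constant; R² undefined")
        self.scale_min_ = X.min(axis=0)
        self.scale_max_ = X.max(axis=0)
        Xs = self._transform_components(X)
        if np.allclose(Xs, Xs[0]):
            raise ValueError(
                "rank-deficient predictors: all component rows identical; "
                "no direction to fit"
            )

        if self.constraint == "unconstrained":
            r2, beta = _subset_ols(Xs, y, (0, 1, 2))
            w = self._direction_to_weights(beta, (0, 1, 2))
        else:
            w, r2 = self._fit_nonneg(Xs, y)

        weights = DIWeights(*w).normalized()
        di = compute_di(Xs, weights)
        r2_line, slope, intercept = _r2_with_intercept(di, y)
        self.weights_ = weights
        self.di_ = di
        self.r2_ = r2_line
        self.slope_ = slope
        self.intercept_ = intercept
        self.n_features_in_ = 3
        return self

    @staticmethod
    def _direction_to_weights(beta: np.ndarray, idx) -> np.ndarray:
        """Embed an OLS direction into weight space, flipping sign if needed.

        R² is invariant to the sign of the combination, so a direction whose
        coefficients are all nonpositive is represented by its negation.
        """
        w = np.zeros(3)
        b = np.array(beta, dtype=float)
        if b.sum() < 0:
            b = -b
        if np.allclose(b, 0):
            raise ValueError("degenerate fit: zero coefficient direction")
        w[list(idx)] = b
        return w

    @staticmethod
    def _fit_nonneg(X: np.ndarray, y: np.ndarray):
        """Exact nonnegative-direction optimum via face enumeration.

        The squared DI–EPS correlation is scale-invariant, so a weight
        direction is feasible iff some positive multiple of it is
        nonnegative, i.e. its coefficients share one sign.  The constrained
        optimum is either the full unconstrained direction (when feasible)
        or the best feasible solution on a face with some weights pinned to
        zero; enumerating every nonempty subset of the three components is
        exhaustive.  Ties prefer fewer zero weights.
        """
        best = None
        for k in (3, 2, 1):
            for idx in combinations(range(3), k):
                if np.ptp(X[:, list(idx)], axis=0).max() == 0:
                    continue  # constant subset: no correlation to fit
                r2, beta = _subset_ols(X, y, idx)
                feasible = np.all(beta >= -1e-12) or np.all(beta <= 1e-12)
                if not feasible:
                    continue
                if np.allclose(beta, 0):
                    continue
                # strict > keeps the first (largest-support) optimum on ties
                if best is None or r2 > best[0] + 1e-15:
                    w = DispersionIndexRegressor._direction_to_weights(beta, idx)
                    best = (r2, w)
        if best is None:
            raise ValueError("no feasible nonnegative weight direction found")
        return best[1], best[0]

    def transform(self, X) -> np.ndarray:
        """DI value of each observation under the fitted weights."""
        check_is_fitted(self, "weights_")
        X = check_array(X, ensure_min_features=3)
        return compute_di(self._transform_components(X), self.weights_)

    def predict(self, X) -> np.ndarray:
        """Predicted EPS via the fitted linear DI–EPS map."""
        return self.intercept_ + self.slope_ * self.transform(X)


def fit_weights(components, eps, constraint: str = "nonneg",
                scaling: str = "raw", doses=None, strains=None) -> DIFitResult:
    """Functional wrapper around :class:`DispersionIndexRegressor`.

    ``components`` is (n, 3) in the order (od, sbr, roughness); ``eps`` is
    the response.  When per-observation ``doses`` (and optionally
    ``strains``) are given, per-strain DI-vs-dose OLS fits are included.
    """
    est = DispersionIndexRegressor(constraint=constraint, scaling=scaling)
    est.fit(np.asarray(components, dtype=float), np.asarray(eps, dtype=float))
    r2_dose = {}
    if doses is not None:
        r2_dose = evaluate_dose_fit(est.di_, doses, strains)
    return DIFitResult(weights=est.weights_, di_values=est.di_, r2_eps=est.r2_,
                       slope=est.slope_, intercept=est.intercept_,
                       r2_dose_by_strain=r2_dose)


def evaluate_dose_fit(di_values, doses, strains=None) -> dict:
    """Per-strain OLS of DI on dose: ``{strain: (slope, r2)}``.

    Requires at least 3 distinct dose levels per strain.  A constant DI
    yields slope 0 and r² = 0.
    """
    di = np.asarray(di_values, dtype=float)
    d = np.asarray(doses, dtype=float)
    s = np.asarray(["all"] * len(di) if strains is None else strains)
    out = {}
    for strain in dict.fromkeys(s):  # preserve order
        sel = s == strain
        if len(np.unique(d[sel])) < 3:
            raise ValueError(f"strain {strain!r}: need >= 3 dose levels")
        if np.ptp(di[sel]) == 0:
            out[strain] = (0.0, 0.0)
            continue
        fit = stats.linregress(d[sel], di[sel])
        out[strain] = (float(fit.slope), float(fit.rvalue**2))
    return out
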