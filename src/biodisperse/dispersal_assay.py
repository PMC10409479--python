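"""Statistics for OD600-based biofilm dispersal dose–response assays.

Dispersed cells released into the bulk liquid raise its optical density, so
the assay reads OD600 of the suspension at each signal dose.  This module
summarizes replicate readings, tests dose-vs-control differences with a
two-sample t-test (pooled-variance Student by default, Welch by flag), and
fits the linear dose trend of the mean OD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DispersalRecord",
    "TestResult",
    "summarize_od",
    "two_sample_t",
    "dose_trend",
    "compare_to_control",
    "holm_adjust",
]

ALPHA = 0.05


@dataclass(frozen=True)
class DispersalRecord:
    """Replicate OD600 readings for one (strain, dose) condition."""

    strain: str
    dose: float
    replicates: tuple[float, ...]
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class TestResult:
    """Two-tailed t-test outcome; ``significant`` is judged at α = 0.05."""

    statistic: float
    df: float
    p: float
    significant: bool


def summarize_od(replicates, strain: str = "", dose: float = 0.0) -> DispersalRecord:
    """Mean and sample standard deviation (n−1) of OD600 replicates.

    With a single replicate the mean is defined but the sd is reported as
    NaN (undefined), never as 0.
    """
    reps = tuple(float(r) for r in replicates)
    if len(reps) == 0:
        raise ValueError("no replicates")
    if any(r < 0 for r in reps):
        raise ValueError("OD600 readings must be nonnegative")
    arr = np.asarray(reps)
    sd = float(arr.std(ddof=1)) if len(reps) > 1 else float("nan")
    return DispersalRecord(strain=strain, dose=dose, replicates=reps,
                           mean=float(arr.mean()), sd=sd, n=len(reps))


def two_sample_t(mean1: float, sd1: float, n1: int,
                 mean2: float, sd2: float, n2: int,
                 variant: str = "student") -> TestResult:
    """Two-tailed two-sample t-test from summary statistics.

    ``variant="student"`` pools the variances (df = n1 + n2 − 2), matching
    the equal-variance test of common spreadsheet usage; ``"welch"`` uses
    the Welch–Satterthwaite approximation.  When both groups have zero
    spread and equal means, t = 0 and p = 1 by convention.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 replicates per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return TestResult(statistic=0.0, df=float(n1 + n2 - 2), p=1.0,
                              significant=False)
        raise ValueError("zero variance in both groups with unequal means")
    if variant == "student":
        equal_var = True
    elif variant == "welch":
        equal_var = False
    else:
        raise ValueError(f"unknown variant {variant!r}")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:  # Welch–Satterthwaite approximation
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(res.pvalue)
    return TestResult(statistic=float(res.statistic), df=df, p=p,
                      significant=p < ALPHA)


def dose_trend(doses, means) -> tuple[float, float]:
    """OLS of mean OD on dose: (slope, r²).  Slope sign gives the direction."""
    d = np.asarray(doses, dtype=float)
    m = np.asarray(means, dtype=float)
    if len(d) < 3:
        raise ValueError("need at least 3 dose levels for a trend")
    if np.ptp(d) == 0:
        raise ValueError("all doses equal: trend undefined")
    fit = stats.linregress(d, m)
    return float(fit.slope), float(fit.rvalue**2)


def compare_to_control(records, control_dose: float = 0.0,
                       variant: str = "student", holm: bool = False):
    """t-test of every dosed condition against the strain's control.

    ``records`` is an iterable of :class:`DispersalRecord`.  Returns a list
    of ``(record, TestResult)`` pairs for every non-control record whose
    strain has a control at ``control_dose``.  With ``holm=True`` the
    p-values are Holm-adjusted before the significance call.
    """
    recs = list(records)
    controls = {r.strain: r for r in recs if r.dose == control_dose}
    pairs = []
    for r in recs:
        if r.dose == control_dose or r.strain not in controls:
            continue
        c = controls[r.strain]
        pairs.append((r, two_sample_t(c.mean, c.sd, c.n, r.mean, r.sd, r.n,
                                      variant=variant)))
    if holm and pairs:
        adj = holm_adjust([t.p for _, t in pairs])
        pairs = [
            (r, TestResult(t.statistic, t.df, p_adj, p_adj < ALPHA))
            for (r, t), p_adj in zip(pairs, adj)
        ]
    return pairs


def holm_adjust(pvalues):
    """Holm step-down adjusted p-values (statsmodels implementation)."""
    from statsmodels.stats.multitest import multipletests

    if len(pvalues) == 0:
        return []
    _, adj, _, _ = multipletests(pvalues, method="holm")
    return [float(min(1.0, p)) for p in adj]
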