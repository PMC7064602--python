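"""Accuracy diagnostics for identified peptide lists.

Three orthogonal checks, all consuming *external* annotations (an HLA
binding predictor's p-values, a hydrophobicity-index calculator's output,
observed retention times) — the predictors themselves are out of scope:

* fraction of predicted HLA binders (p-value <= 0.05): correct HLA ligand
  lists are dominated by predicted binders;
* ordinary least-squares regression of observed retention time (RT) on
  the calculated hydrophobicity index (HI): correct identifications sit
  close to the regression line, so the residual standard error measures
  list quality;
* a one-sided F-test comparing the residual variances of two peptide
  lists around their regression lines (putatively noisier list first).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PeptideAnnotation",
    "RegressionResult",
    "binder_fraction",
    "rt_hi_regression",
    "variance_f_test",
]


@dataclass(slots=True)
class PeptideAnnotation:
    """External annotations of one peptide.

    ``rt_mean`` is the arithmetic mean retention time (minutes) over a
    peptide's repeated observations in a sample; ``hi`` the predicted
    hydrophobicity index (%ACN); ``binder_pvalue`` an HLA binding
    predictor's p-value.
    """

    peptide: str
    binder_pvalue: float = float("nan")
    hi: float = float("nan")
    rt_mean: float = float("nan")


@dataclass(slots=True)
class RegressionResult:
    slope: float
    intercept: float
    residuals: np.ndarray
    residual_se: float

    @property
    def abs_errors(self) -> np.ndarray:
        return np.abs(self.residuals)


def binder_fraction(
    annotations: list[PeptideAnnotation], threshold: float = 0.05
) -> float:
    """Fraction of peptides with binder p-value <= ``threshold`` (inclusive)."""
    pvals = [a.binder_pvalue for a in annotations if a.binder_pvalue == a.binder_pvalue]
    for p in pvals:
        if not 0 <= p <= 1:
            raise ValueError(f"binder p-value {p} outside [0, 1]")
    if not pvals:
        warnings.warn("no binder p-values: fraction defined as 0", UserWarning)
        return 0.0
    return sum(p <= threshold for p in pvals) / len(pvals)


def rt_hi_regression(annotations: list[PeptideAnnotation]) -> RegressionResult:
    """OLS regression of observed retention time on hydrophobicity index.

    Only annotations with both HI and RT present contribute; at least 3
    points with non-zero HI variance are required.  ``residual_se`` is the
    residual standard error sqrt(SSR / (n - 2)); the signed residuals are
    exposed so that their absolute errors can be plotted or fed into
    :func:`variance_f_test`.
    """
    pairs = [
        (a.hi, a.rt_mean)
        for a in annotations
        if a.hi == a.hi and a.rt_mean == a.rt_mean
    ]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 annotated peptides, got {len(pairs)}")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in hydrophobicity index")
    fit = stats.linregress(x, y)
    residuals = y - (fit.intercept + fit.slope * x)
    dof = len(x) - 2
    residual_se = float(np.sqrt(np.sum(residuals**2) / dof)) if dof > 0 else 0.0
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residuals=residuals,
        residual_se=residual_se,
    )


def variance_f_test(
    residualsA: np.ndarray | list[float], residualsB: np.ndarray | list[float]
) -> tuple[float, float]:
    """One-sided F-test that list A's residual variance exceeds list B's.

    F = var(A) / var(B) with sample variances (n-1 denominator); the
    p-value is the upper tail of the F distribution with
    (nA - 1, nB - 1) degrees of freedom.  By convention A is the list
    hypothesised to be noisier.  A constant B yields an infinite F with
    p = 0.
    """
    a = np.asarray(residualsA, dtype=float)
    b = np.asarray(residualsB, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each residual list needs >= 2 values")
    var_a = float(np.var(a, ddof=1))
    var_b = float(np.var(b, ddof=1))
    if var_b == 0:
        warnings.warn("zero variance in reference list: F is infinite", UserWarning)
        return float("inf"), 0.0
    f_statistic = var_a / var_b
    p_value = float(stats.f.sf(f_statistic, len(a) - 1, len(b) - 1))
    return f_statistic, p_value
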