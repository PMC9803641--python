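"""Multiple-testing machinery: effective number of tests and FDR.

Metabolite panels are strongly correlated, so a Bonferroni correction at
the full panel size is too severe.  The effective number of independent
tests (Meff) is estimated from the eigenvalue spectrum of the metabolite
correlation matrix with the Li & Ji (2005) estimator

    Meff = sum_i f(lambda_i),   f(x) = 1{x >= 1} + (x - floor(x)),

and the family-wise significance threshold is alpha / Meff.  P values in
[threshold, 0.05) form the "nominal" tier.

With fewer samples than metabolites the sample correlation matrix is
rank-deficient and its spectrum is dominated by estimation noise, which
collapses Meff towards the sample rank and makes alpha/Meff badly
anticonservative.  :func:`metabolite_correlation` therefore applies
Schaefer-Strimmer shrinkage of the correlation matrix towards the
identity (the corpcor convention) before the spectrum is taken; under an
independent metabolome this restores Meff ~ m.  An externally supplied
Meff override (:func:`from_meff`) reproduces published thresholds
verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

NOMINAL_ALPHA = 0.05


@dataclass
class MultiplicityResult:
    """Meff, the family-wise level, and the two significance bands."""

    meff: float
    alpha: float
    threshold: float
    nominal_cut: float = NOMINAL_ALPHA
    eigenvalues: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not np.isclose(self.threshold, self.alpha / self.meff):
            raise ValueError("threshold must equal alpha / meff")

    @property
    def nominal_band(self) -> tuple[float, float]:
        """P values in [threshold, nominal_cut) are nominally significant."""
        return (self.threshold, self.nominal_cut)

    def summary(self) -> dict:
        out = {
            "meff": float(self.meff),
            "alpha": float(self.alpha),
            "threshold": float(self.threshold),
            "nominal_cut": float(self.nominal_cut),
        }
        if self.eigenvalues is not None:
            ev = np.asarray(self.eigenvalues)
            out["n_eigenvalues"] = int(ev.size)
            out["eigenvalue_sum"] = float(ev.sum())
            out["eigenvalue_max"] = float(ev.max())
        return out


def significance_threshold(alpha: float, meff: float) -> float:
    """The Bonferroni-at-Meff threshold alpha / Meff."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if meff < 1:
        raise ValueError("meff must be >= 1")
    return alpha / meff


def from_meff(meff: float, alpha: float = 0.05) -> MultiplicityResult:
    """Bands for an externally supplied effective test count."""
    return MultiplicityResult(meff=float(meff), alpha=alpha, threshold=significance_threshold(alpha, meff))


def _liji_sum(eigenvalues: np.ndarray) -> float:
    lam = np.clip(eigenvalues, 0.0, None)  # clamp round-off negatives
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


def effective_tests(corr: np.ndarray | pd.DataFrame, alpha: float = 0.05) -> MultiplicityResult:
    """Li-Ji effective number of tests from a correlation matrix.

    The input must be square, symmetric, with unit diagonal and entries
    in [-1, 1].  Identity -> Meff equals the dimension; the all-ones
    matrix -> Meff = 1.
    """
    c = np.asarray(corr, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.nanmax(np.abs(c)) > 1 + 1e-8:
        raise ValueError("correlation entries must lie in [-1, 1]")
    eigenvalues = np.linalg.eigvalsh(c)
    meff = min(_liji_sum(eigenvalues), float(c.shape[0]))
    meff = max(meff, 1.0)
    return MultiplicityResult(
        meff=meff,
        alpha=alpha,
        threshold=significance_threshold(alpha, meff),
        eigenvalues=eigenvalues,
    )


def metabolite_correlation(values: pd.DataFrame, shrinkage: float | str | None = "auto") -> tuple[np.ndarray, float]:
    """Pearson correlation of the (log) abundance matrix, optionally shrunk.

    ``shrinkage="auto"`` estimates the Schaefer-Strimmer intensity

        lambda* = sum_{i!=j} Var(r_ij) / sum_{i!=j} r_ij^2

    and returns (1 - lambda*) R + lambda* I.  ``shrinkage=None`` (or 0)
    returns the plain sample correlation; a float in [0, 1] fixes the
    intensity.  Columns with zero variance are rejected.
    """
    x = values.to_numpy(dtype=float)
    n, m = x.shape
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(values.columns[sd == 0])[:5]
        raise ValueError(f"zero-variance metabolites in correlation input: {bad}")
    xs = (x - x.mean(axis=0)) / sd
    r = xs.T @ xs / (n - 1)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)

    if shrinkage is None or shrinkage == 0:
        lam = 0.0
    elif shrinkage == "auto":
        # Schaefer & Strimmer (2005): unbiased-ish moment estimate of the
        # optimal intensity for shrinking towards the identity target.
        w_bar = r * (n - 1) / n
        sum_w2 = (xs * xs).T @ (xs * xs)  # sum_k (xs_ki xs_kj)^2
        var_r = n / (n - 1) ** 3 * (sum_w2 - n * w_bar**2)
        off = ~np.eye(m, dtype=bool)
        denom = float(np.sum(r[off] ** 2))
        lam = 1.0 if denom == 0 else float(np.clip(np.sum(var_r[off]) / denom, 0.0, 1.0))
    else:
        lam = float(shrinkage)
        if not 0 <= lam <= 1:
            raise ValueError("shrinkage intensity must be in [0, 1]")

    if lam > 0:
        r = (1 - lam) * r
        np.fill_diagonal(r, 1.0)
    return r, lam


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
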