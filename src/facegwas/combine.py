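"""Combined test of dependent tests (Brown's method with the
Kost-McDermott covariance approximation).

Fisher's statistic T = sum_i -2 log P_i has mean 2k under the null; when
the k tests are dependent its variance inflates to

    V = 4k + 2 * sum_{i<j} cov(-2 log P_i, -2 log P_j),

and T is referred to a scaled chi-squared distribution with scale
c = V / (2E) and degrees of freedom f = 2 E^2 / V.  The covariance of a
pair of -2 log P statistics whose underlying test statistics are bivariate
normal with correlation r is approximated by the cubic polynomial

    cov ~= 3.263 r + 0.71 r^2 + 0.027 r^3,

which matches exact numerical integration (one-sided upper-tail p-values)
to better than 2e-4 across -0.98 < r < 0.98.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import roots_hermitenorm
from scipy.stats import chi2, norm

from .containers import CombinedTestResult

_TINY_P = np.finfo(float).tiny


def cov_polynomial(r) -> np.ndarray | float:
    """Kost-McDermott polynomial approximation of
    cov(-2 log P_i, -2 log P_j) at test-statistic correlation r.

    Values of |r| above 0.98 are flagged with a warning: the approximation
    is validated only on the open interval (-0.98, 0.98).
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0):
        raise ValueError("correlations must lie in [-1, 1]")
    if np.any(np.abs(r) > 0.98):
        warnings.warn("covariance polynomial used outside its validated range |r| <= 0.98")
    out = 3.263 * r + 0.71 * r**2 + 0.027 * r**3
    return out.item() if out.ndim == 0 else out


def cov_exact(r: float, n_nodes: int = 201) -> float:
    """Covariance of (-2 log P_i, -2 log P_j) by 2-D Gauss-Hermite
    quadrature over a bivariate standard normal with correlation r.

    P is the one-sided upper-tail p-value of each coordinate (the Brown
    setting).  Quadrature error is below 1e-5 at the default node count.
    """
    if abs(r) >= 1.0:
        raise ValueError("|r| must be < 1 for exact integration")
    x, w = roots_hermitenorm(n_nodes)
    w = w / np.sqrt(2.0 * np.pi)
    f1 = -2.0 * norm.logsf(x)
    z2 = r * x[:, None] + np.sqrt(1.0 - r * r) * x[None, :]
    f2 = -2.0 * norm.logsf(z2)
    e12 = w @ ((f1[:, None] * f2) @ w)
    return float(e12 - 4.0)  # E[-2 log P] = 2 for each margin


def combined_test(p_values, corr=None) -> CombinedTestResult:
    """Combine k dependent p-values into one scaled chi-squared test.

    ``corr`` is the k x k correlation matrix of the underlying test
    statistics (identity if omitted, which reduces the procedure exactly
    to Fisher's method).  Zero p-values are clipped to the smallest
    positive float with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("zero p-value clipped to the smallest positive float")
        p = np.maximum(p, _TINY_P)
    k = p.size
    T = float(np.sum(-2.0 * np.log(p)))
    E = 2.0 * k
    if corr is None:
        cov_sum = 0.0
    else:
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (k, k):
            raise ValueError(f"correlation matrix must be {k} x {k}")
        iu = np.triu_indices(k, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cov_sum = float(np.sum(cov_polynomial(corr[iu])))
    V = 4.0 * k + 2.0 * cov_sum
    c = V / (2.0 * E)
    f = 2.0 * E * E / V
    p_comb = float(chi2.sf(T / c, f))
    return CombinedTestResult(
        statistic=T, k=k, expectation=E, variance=V, scale=c, dof=f, p_value=p_comb
    )


def replication_combine(
    cohort_pvalues: dict[str, dict[str, float]],
    cohort_correlations: dict[str, "np.ndarray"],
    cohort_phenotypes: dict[str, list[str]] | None = None,
) -> CombinedTestResult:
    """Two-stage combination of replication evidence for one SNP.

    Stage 1 combines the per-phenotype p-values within each cohort using
    that cohort's phenotype correlation matrix; stage 2 combines the
    per-cohort combined p-values treating cohorts as independent (distinct
    samples), i.e. by Fisher's method.

    ``cohort_pvalues`` maps cohort -> {phenotype: p}; ``cohort_correlations``
    maps cohort -> correlation matrix aligned with ``cohort_phenotypes``
    (or with the sorted phenotype names when not given).  A missing
    correlation entry is an error - there is no silent default.
    """
    stage1 = []
    for cohort, pmap in cohort_pvalues.items():
        if not pmap:
            continue
        phenos = (
            cohort_phenotypes[cohort] if cohort_phenotypes else sorted(pmap)
        )
        missing = [ph for ph in pmap if ph not in phenos]
        if missing:
            raise KeyError(f"no correlation entry for phenotypes {missing} in cohort {cohort}")
        if len(pmap) == 1:
            stage1.append(next(iter(pmap.values())))
            continue
        used = [ph for ph in phenos if ph in pmap]
        corr = np.asarray(cohort_correlations[cohort], dtype=float)
        if corr.shape != (len(phenos), len(phenos)):
            raise KeyError(
                f"correlation matrix for cohort {cohort} has shape {corr.shape}, "
                f"expected {(len(phenos), len(phenos))}"
            )
        sel = [phenos.index(ph) for ph in used]
        sub = corr[np.ix_(sel, sel)]
        ps = np.array([pmap[ph] for ph in used])
        stage1.append(combined_test(ps, sub).p_value)
    if not stage1:
        raise ValueError("no cohort reported any p-value")
    if len(stage1) == 1:
        # single cohort: pass its combined evidence through unchanged
        res = stage1[0]
        return CombinedTestResult(
            statistic=-2.0 * np.log(max(res, _TINY_P)), k=1, expectation=2.0,
            variance=4.0, scale=1.0, dof=2.0, p_value=float(res),
        )
    return combined_test(np.array(stage1))
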