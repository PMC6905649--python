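"""Effective number of independent traits, Bonferroni thresholds, and
analytic power of the 1-df additive association test.

Correlated traits make a per-trait Bonferroni correction over-conservative;
the spectral-decomposition estimators of Li & Ji and Nyholt summarize the
eigenvalue spectrum of the trait correlation matrix into an effective test
count Meff, and the study-wide threshold becomes alpha / Meff.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2, ncx2, norm

from .containers import EffectiveTestCount


def effective_tests(
    corr: np.ndarray, method: str = "li_ji", psd_tol: float = 0.05
) -> EffectiveTestCount:
    """Effective number of independent tests from a trait correlation matrix.

    ``li_ji``: Meff = sum over eigenvalues of I(lambda >= 1) +
    (lambda - floor(lambda)).  ``nyholt``: Meff = 1 + (M - 1) *
    (1 - var(lambda) / M).  The matrix must be symmetric with unit
    diagonal.  Pairwise-complete correlation matrices can be mildly
    indefinite; eigenvalues above ``-psd_tol`` are clipped to zero,
    anything below that is rejected as not positive semi-definite.
    """
    corr = np.asarray(corr, dtype=float)
    M = corr.shape[0]
    if corr.shape != (M, M) or not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be square and symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-6):
        raise ValueError("correlation matrix must have unit diagonal")
    lam = np.linalg.eigvalsh((corr + corr.T) / 2.0)
    if lam.min() < -psd_tol:
        raise ValueError(f"matrix not positive semi-definite (min eigenvalue {lam.min():.3g})")
    lam = np.clip(lam, 0.0, None)
    if method == "li_ji":
        # round before flooring: an eigenvalue numerically just below an
        # integer must not contribute a spurious fractional part of ~1
        lam_r = np.round(lam, 10)
        meff = float(np.sum((lam_r >= 1.0).astype(float) + (lam_r - np.floor(lam_r))))
    elif method == "nyholt":
        meff = float(1.0 + (M - 1) * (1.0 - np.var(lam, ddof=1) / M))
    else:
        raise ValueError(f"unknown method {method!r}; use 'li_ji' or 'nyholt'")
    return EffectiveTestCount(eigenvalues=lam[::-1], meff=meff, method=method)


def bonferroni_threshold(alpha: float, m: int) -> tuple[float, float]:
    """alpha / m, returned as (full precision, rounded to 2 significant
    figures)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    full = alpha / m
    exponent = np.floor(np.log10(full))
    rounded = round(full / 10**exponent, 1) * 10**exponent
    return full, float(rounded)


def analytic_power(
    n: int, r2: float, alpha: float, ncp_form: str = "exact", reference: str = "normal"
) -> float:
    """Power of the two-sided 1-df additive-model test.

    The noncentrality is n * r2 / (1 - r2) for a variant explaining a
    fraction ``r2`` of phenotypic variance in ``n`` samples
    (``ncp_form='simple'`` uses n * r2).  The default reference is the
    two-tailed normal form

        power = Phi(sqrt(ncp) - z_{1-alpha/2}) + Phi(-sqrt(ncp) - z_{1-alpha/2});

    ``reference='ncx2'`` uses the exact noncentral chi-squared tail.  The
    two agree to about 4 decimals at realistic parameters.
    """
    if not (n > 0 and 0.0 <= r2 < 1.0 and 0.0 < alpha < 1.0):
        raise ValueError("need n > 0, r2 in [0, 1), alpha in (0, 1)")
    ncp = n * r2 / (1.0 - r2) if ncp_form == "exact" else n * r2
    if reference == "normal":
        z_crit = norm.isf(alpha / 2.0)
        s = np.sqrt(ncp)
        return float(norm.cdf(s - z_crit) + norm.cdf(-s - z_crit))
    if reference == "ncx2":
        crit = chi2.isf(alpha, 1)
        return float(ncx2.sf(crit, 1, ncp)) if ncp > 0 else alpha
    raise ValueError(f"unknown reference {reference!r}")
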