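"""Per-cohort variant QC, ancestry principal components, and per-SNP
additive-model association tests.

The association model is ordinary least squares of each (adjusted)
phenotype on effect-allele dosage plus covariates, with a two-sided
t-test on the dosage coefficient.  When the dosage matrix has no missing
entries the scan is vectorized across variants through
Frisch-Waugh-Lovell residualization, which is algebraically identical to
the full per-variant regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .config import RunConfig
from .containers import GenotypePanel, PhenotypeMatrix

log = logging.getLogger("facegwas")

#: Median of the chi-squared distribution with 1 degree of freedom.
CHI2_1_MEDIAN = 0.45493642311957174


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value by full enumeration of
    heterozygote counts conditional on allele counts (no mid-p).

    The p-value is the total probability of all genotype configurations
    with probability no greater than the observed one.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    het_obs = n_het
    # log-probability of each possible het count with same parity as n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    from scipy.special import gammaln

    def logp(h):
        hom_r = (n_rare - h) // 2
        hom_c = n - hom_r - h
        return (
            h * math.log(2.0)
            + gammaln(n + 1) - gammaln(hom_r + 1) - gammaln(h + 1) - gammaln(hom_c + 1)
            - (gammaln(2 * n + 1) - gammaln(n_rare + 1) - gammaln(2 * n - n_rare + 1))
        )

    lps = np.array([logp(int(h)) for h in hets])
    probs = np.exp(lps - lps.max())
    probs /= probs.sum()
    p_obs = probs[np.flatnonzero(hets == het_obs)[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# variant QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    n_input: int
    n_removed_maf: int
    n_removed_call_rate: int
    n_removed_hwe: int
    n_removed_info: int
    n_kept: int


def variant_qc(panel: GenotypePanel, config: RunConfig) -> tuple[GenotypePanel, QCReport]:
    """Remove variants failing MAF, call-rate, HWE, or info thresholds.

    HWE uses the exact enumeration test on hard genotype counts (dosages
    rounded); the info filter applies only where an info score is present.
    """
    freq = panel.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    cr = panel.call_rate()
    hwe = np.ones(panel.n_variants)
    g = panel.dosages
    for j in range(panel.n_variants):
        col = g[:, j]
        col = col[~np.isnan(col)]
        counts = np.round(col).astype(int)
        hwe[j] = hwe_exact_p(
            int((counts == 0).sum()), int((counts == 1).sum()), int((counts == 2).sum())
        )
    pass_maf = maf > config.maf_min
    pass_cr = cr > config.call_rate_min
    pass_hwe = hwe > config.hwe_p_min
    if "info" in panel.variants.columns:
        info = panel.variants["info"].to_numpy(dtype=float)
        pass_info = np.isnan(info) | (info > config.info_min)
    else:
        pass_info = np.ones(panel.n_variants, dtype=bool)
    keep = pass_maf & pass_cr & pass_hwe & pass_info
    report = QCReport(
        n_input=panel.n_variants,
        n_removed_maf=int((~pass_maf).sum()),
        n_removed_call_rate=int((~pass_cr).sum()),
        n_removed_hwe=int((~pass_hwe).sum()),
        n_removed_info=int((~pass_info).sum()),
        n_kept=int(keep.sum()),
    )
    log.info(
        "variant_qc: %d -> %d (maf -%d, call rate -%d, hwe -%d, info -%d)",
        report.n_input, report.n_kept, report.n_removed_maf,
        report.n_removed_call_rate, report.n_removed_hwe, report.n_removed_info,
    )
    return panel.take_variants(keep), report


# ---------------------------------------------------------------------------
# genotype principal components
# ---------------------------------------------------------------------------

def genotype_pcs(panel: GenotypePanel, k: int) -> pd.DataFrame:
    """Principal-component scores of the column-standardized dosage matrix.

    Zero-variance variants are dropped before standardization; missing
    dosages are mean-imputed (zero after centering).  The sign convention
    fixes the largest-magnitude loading of each component positive, making
    the decomposition deterministic.
    """
    if k == 0:
        return pd.DataFrame(index=pd.Index(panel.samples, name="sample"))
    if k > min(panel.n_samples, panel.n_variants):
        raise ValueError("k exceeds min(samples, variants)")
    X = panel.dosages.copy()
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=0)
    keep = sd > 0
    X = (X[:, keep] - mu[keep]) / sd[keep]
    X[np.isnan(X)] = 0.0
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * S[:k]
    for c in range(k):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            scores[:, c] = -scores[:, c]
    return pd.DataFrame(
        scores, index=pd.Index(panel.samples, name="sample"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------

def exclude_mz_cotwins(covariates: pd.DataFrame) -> list[str]:
    """Samples to keep after dropping one member of each monozygotic pair."""
    keep, seen = [], set()
    for s, row in covariates.iterrows():
        if row.get("zygosity") == "MZ":
            if row["twin_pair"] in seen:
                continue
            seen.add(row["twin_pair"])
        keep.append(s)
    return keep


@dataclass
class AssocStats:
    """Per (variant, phenotype) association results plus per-phenotype
    genomic inflation."""

    table: pd.DataFrame          # SNP CHR POS EA OA EAF PHENOTYPE BETA SE P N
    lambda_gc: pd.Series         # per phenotype

    def for_phenotype(self, phenotype: str) -> pd.DataFrame:
        return self.table[self.table["PHENOTYPE"] == phenotype]


def _scan_one_phenotype(y, G, C):
    """Vectorized OLS of y on each column of G with covariates C.

    Returns beta, se, p, n.  Requires complete data (no NaN).
    """
    n, m = G.shape
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)
    sxx = (G_r**2).sum(axis=0)
    sxy = G_r.T @ y_r
    ok = sxx > 1e-12
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    beta[ok] = sxy[ok] / sxx[ok]
    df = n - C.shape[1] - 1
    syy = (y_r**2).sum()
    sse = syy - beta[ok] ** 2 * sxx[ok]
    sigma2 = np.maximum(sse, 0.0) / df
    se[ok] = np.sqrt(sigma2 / sxx[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta / se
    p = 2.0 * t_dist.sf(np.abs(tval), df)
    return beta, se, p, np.full(m, n)


def gwas_linear(
    panel: GenotypePanel,
    pheno: PhenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    covariate_columns: list[str] | None = None,
) -> AssocStats:
    """Per variant x phenotype additive-model linear regression.

    The model is phenotype ~ dosage + covariates (+ intercept) on complete
    cases; p-values are two-sided t-tests on the dosage coefficient.  The
    genomic inflation factor per phenotype is median(z^2) / 0.4549.
    Entries with fewer complete cases than covariates + 2 are reported
    missing.
    """
    samples = pheno.data.index
    idx = {s: i for i, s in enumerate(panel.samples)}
    rows_panel = np.array([idx[s] for s in samples])
    G_all = panel.dosages[rows_panel]
    if covariates is not None:
        if covariate_columns is None:
            covariate_columns = [c for c in ("sex", "age") if c in covariates.columns]
            covariate_columns += [c for c in covariates.columns if c.startswith("PC")]
        C_all = covariates.loc[samples, covariate_columns].to_numpy(dtype=float)
    else:
        C_all = np.empty((len(samples), 0))
    C_all = np.column_stack([np.ones(len(samples)), C_all])

    freq = panel.allele_freq()
    var_meta = panel.variants
    out_rows = []
    lambdas = {}
    g_has_nan = np.isnan(G_all).any()
    for col in pheno.data.columns:
        y = pheno.data[col].to_numpy(dtype=float)
        ok = ~(np.isnan(y) | np.isnan(C_all).any(axis=1))
        if g_has_nan:
            beta, se, p, nn = _scan_missing(y, G_all, C_all, ok)
        else:
            beta, se, p, nn = _scan_one_phenotype(y[ok], G_all[ok], C_all[ok])
        with np.errstate(divide="ignore", invalid="ignore"):
            z2 = (beta / se) ** 2
        z2 = z2[np.isfinite(z2)]
        lambdas[col] = float(np.median(z2) / CHI2_1_MEDIAN) if z2.size else np.nan
        out_rows.append(
            pd.DataFrame(
                {
                    "SNP": var_meta["id"].to_numpy(),
                    "CHR": var_meta["chrom"].to_numpy(),
                    "POS": var_meta["pos"].to_numpy(),
                    "EA": var_meta["ea"].to_numpy(),
                    "OA": var_meta["oa"].to_numpy(),
                    "EAF": freq,
                    "PHENOTYPE": col,
                    "BETA": beta,
                    "SE": se,
                    "P": p,
                    "N": nn,
                }
            )
        )
    table = pd.concat(out_rows, ignore_index=True)
    return AssocStats(table=table, lambda_gc=pd.Series(lambdas, name="lambda"))


def _scan_missing(y, G, C, ok_base):
    """Per-variant complete-case fallback when dosages contain missing."""
    m = G.shape[1]
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    p = np.full(m, np.nan)
    nn = np.zeros(m, dtype=int)
    p_cov = C.shape[1]
    for j in range(m):
        ok = ok_base & ~np.isnan(G[:, j])
        nj = int(ok.sum())
        nn[j] = nj
        if nj < p_cov + 2:
            continue
        X = np.column_stack([G[ok, j], C[ok]])
        b, _, rank, _ = np.linalg.lstsq(X, y[ok], rcond=None)
        resid = y[ok] - X @ b
        df = nj - X.shape[1]
        if df <= 0 or rank < X.shape[1]:
            continue
        sigma2 = (resid**2).sum() / df
        XtX_inv = np.linalg.inv(X.T @ X)
        s = math.sqrt(max(sigma2 * XtX_inv[0, 0], 0.0))
        beta[j], se[j] = b[0], s
        if s > 0:
            p[j] = 2.0 * t_dist.sf(abs(b[0] / s), df)
    return beta, se, p, nn
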