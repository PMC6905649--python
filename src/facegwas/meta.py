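"""Inverse-variance fixed-effect meta-analysis with Cochran's Q
heterogeneity testing."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

log = logging.getLogger("facegwas")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _strand_ambiguous(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def harmonize_to(ref_ea: str, ref_oa: str, ea: str, oa: str) -> float | None:
    """Sign to apply to a cohort beta so it is on the reference EA scale.

    Returns +1 (aligned), -1 (alleles swapped -> flip beta and EAF), or
    None when the allele pair cannot be reconciled (including
    strand-ambiguous mismatches, which are unresolvable without frequency
    information and are dropped by the caller).
    """
    if (ea, oa) == (ref_ea, ref_oa):
        return 1.0
    if (ea, oa) == (ref_oa, ref_ea):
        return -1.0
    flip = (_COMPLEMENT.get(ea), _COMPLEMENT.get(oa))
    if flip == (ref_ea, ref_oa) and not _strand_ambiguous(ea, oa):
        return 1.0
    if flip == (ref_oa, ref_ea) and not _strand_ambiguous(ea, oa):
        return -1.0
    return None


def cochran_q(betas: np.ndarray, ses: np.ndarray) -> tuple[float, int, float]:
    """Cochran's Q = sum w_i (beta_i - pooled)^2 with chi^2_{k-1} p-value.

    Requires at least two cohorts; returns (nan, 0, nan) otherwise.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    k = len(betas)
    if k < 2:
        return np.nan, 0, np.nan
    w = 1.0 / ses**2
    pooled = (w * betas).sum() / w.sum()
    Q = float((w * (betas - pooled) ** 2).sum())
    df = k - 1
    return Q, df, float(chi2.sf(Q, df))


def ivw_meta(cohort_stats: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effect inverse-variance meta-analysis across cohorts.

    Input is a mapping cohort name -> summary table with the standard
    columns (SNP CHR POS EA OA EAF PHENOTYPE BETA SE P N).  Alleles are
    harmonized to the first cohort reporting each (SNP, PHENOTYPE); rows
    whose alleles cannot be reconciled (strand-ambiguous mismatch) are
    dropped with a log entry.  Variants present in only a subset of
    cohorts are meta-analyzed over the cohorts that report them.

    Output adds pooled BETA/SE, normal-approximation Z and P, Cochran's Q
    with its degrees of freedom and p-value, and the contributing-cohort
    count K.
    """
    frames = []
    for name, df in cohort_stats.items():
        d = df.copy()
        d["_cohort"] = name
        frames.append(d)
    allstats = pd.concat(frames, ignore_index=True)
    rows = []
    n_dropped = 0
    for (snp, pheno_name), grp in allstats.groupby(["SNP", "PHENOTYPE"], sort=False):
        ref = grp.iloc[0]
        betas, ses, ns, eafs = [], [], [], []
        for _, r in grp.iterrows():
            sign = harmonize_to(ref["EA"], ref["OA"], r["EA"], r["OA"])
            if sign is None:
                n_dropped += 1
                log.info("ivw_meta: dropping %s/%s from %s (unresolvable alleles %s/%s)",
                         snp, pheno_name, r["_cohort"], r["EA"], r["OA"])
                continue
            if not (np.isfinite(r["BETA"]) and np.isfinite(r["SE"]) and r["SE"] > 0):
                continue
            betas.append(sign * r["BETA"])
            ses.append(r["SE"])
            ns.append(r["N"])
            eafs.append(r["EAF"] if sign > 0 else 1.0 - r["EAF"])
        if not betas:
            continue
        betas = np.array(betas)
        ses = np.array(ses)
        w = 1.0 / ses**2
        pooled_beta = float((w * betas).sum() / w.sum())
        pooled_se = float(1.0 / np.sqrt(w.sum()))
        z = pooled_beta / pooled_se
        p = float(2.0 * norm.sf(abs(z)))
        Q, qdf, qp = cochran_q(betas, ses)
        rows.append(
            {
                "SNP": snp, "CHR": ref["CHR"], "POS": ref["POS"],
                "EA": ref["EA"], "OA": ref["OA"],
                "EAF": float(np.average(eafs, weights=ns)),
                "PHENOTYPE": pheno_name,
                "BETA": pooled_beta, "SE": pooled_se, "P": p,
                "N": int(np.sum(ns)),
                "Z": z, "Q": Q, "Q_DF": qdf, "Q_P": qp, "K": len(betas),
            }
        )
    if n_dropped:
        log.info("ivw_meta: dropped %d unresolvable rows", n_dropped)
    return pd.DataFrame(rows)
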