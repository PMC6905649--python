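"""Twin-based (Falconer) and SNP-based (Haseman-Elston) heritability.

The twin estimator is h^2 = 2 (r_MZ - r_DZ), contrasting monozygotic and
dizygotic pair correlations.  The SNP estimator regresses phenotype
cross-products of unrelated individuals on the off-diagonal entries of
the genetic relatedness matrix (Haseman-Elston regression) - a
method-of-moments stand-in for restricted maximum likelihood, labelled as
such; its estimates are expected to track, not equal, REML's.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypePanel, PhenotypeMatrix

log = logging.getLogger("facegwas")


@dataclass
class TwinEstimate:
    table: pd.DataFrame  # per phenotype: r_mz, r_dz, h2, h2_clamped, n_mz, n_dz, ci_lo, ci_hi


def _pair_arrays(pheno: pd.DataFrame, pairs: pd.DataFrame, zygosity: str):
    sub = pairs[pairs["zygosity"] == zygosity]
    a = sub["sample1"].to_numpy()
    b = sub["sample2"].to_numpy()
    return pheno.reindex(a).to_numpy(), pheno.reindex(b).to_numpy()


def twin_pairs_from_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Build a (sample1, sample2, zygosity) pair table from a covariate
    table carrying ``zygosity`` and ``twin_pair`` columns."""
    rows = []
    tw = covariates[covariates["zygosity"].isin(["MZ", "DZ"])]
    for pair_id, grp in tw.groupby("twin_pair"):
        if len(grp) == 2:
            rows.append(
                {"sample1": grp.index[0], "sample2": grp.index[1],
                 "zygosity": grp["zygosity"].iloc[0]}
            )
    return pd.DataFrame(rows, columns=["sample1", "sample2", "zygosity"])


def twin_h2(
    pheno: PhenotypeMatrix,
    pairs: pd.DataFrame,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> TwinEstimate:
    """Falconer twin heritability per phenotype: h^2 = 2 (r_MZ - r_DZ).

    Correlations are Pearson over pairs (double-entered symmetrically so
    the estimate does not depend on which co-twin is listed first); pairs
    with a missing co-twin value are dropped.  Raw estimates are reported
    as-is, alongside a [0, 1]-clamped display value and a pair-bootstrap
    confidence interval.  Requires at least 2 MZ and 2 DZ pairs.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for col in pheno.data.columns:
        x = pheno.data[col]
        res = {"phenotype": col}
        corrs, counts, samples_by_z = {}, {}, {}
        for z in ("MZ", "DZ"):
            a, b = _pair_arrays(x, pairs, z)
            ok = ~(np.isnan(a) | np.isnan(b))
            a, b = a[ok], b[ok]
            counts[z] = len(a)
            if len(a) < 2:
                raise ValueError(f"need at least 2 complete {z} pairs (got {len(a)})")
            # double-entry correlation: symmetric in co-twin order
            aa = np.concatenate([a, b])
            bb = np.concatenate([b, a])
            corrs[z] = float(np.corrcoef(aa, bb)[0, 1])
            samples_by_z[z] = (a, b)
        h2 = 2.0 * (corrs["MZ"] - corrs["DZ"])
        boots = np.empty(n_bootstrap)
        for it in range(n_bootstrap):
            vals = {}
            for z in ("MZ", "DZ"):
                a, b = samples_by_z[z]
                idx = rng.integers(len(a), size=len(a))
                aa = np.concatenate([a[idx], b[idx]])
                bb = np.concatenate([b[idx], a[idx]])
                vals[z] = np.corrcoef(aa, bb)[0, 1]
            boots[it] = 2.0 * (vals["MZ"] - vals["DZ"])
        res.update(
            r_mz=corrs["MZ"], r_dz=corrs["DZ"], h2=h2,
            h2_clamped=float(np.clip(h2, 0.0, 1.0)),
            n_mz=counts["MZ"], n_dz=counts["DZ"],
            ci_lo=float(np.percentile(boots, 2.5)),
            ci_hi=float(np.percentile(boots, 97.5)),
        )
        rows.append(res)
    return TwinEstimate(pd.DataFrame(rows).set_index("phenotype"))


# ---------------------------------------------------------------------------
# SNP-based heritability (Haseman-Elston)
# ---------------------------------------------------------------------------

def grm(panel: GenotypePanel) -> np.ndarray:
    """Genetic relatedness matrix of column-standardized dosages.

    G = Z Z^T / M with Z the standardized dosage matrix (missing entries
    zero after centering); the mean diagonal is ~1 by construction.
    """
    X = panel.dosages.copy()
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=0)
    keep = sd > 0
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    Z[np.isnan(Z)] = 0.0
    return Z @ Z.T / keep.sum()


def exclude_related(G: np.ndarray, samples: list[str], threshold: float = 0.05) -> list[str]:
    """Greedy pruning until all GRM off-diagonals are below the threshold."""
    keep = np.ones(len(samples), dtype=bool)
    A = np.abs(G.copy())
    np.fill_diagonal(A, 0.0)
    while True:
        A_k = A[np.ix_(keep, keep)]
        if A_k.size == 0 or A_k.max() < threshold:
            break
        counts = (A >= threshold) & keep[None, :] & keep[:, None]
        worst = np.argmax(counts.sum(axis=1))
        keep[worst] = False
    return [s for s, k in zip(samples, keep) if k]


@dataclass
class SnpEstimate:
    table: pd.DataFrame  # per phenotype: h2_snp, se, n


def snp_h2_he(
    panel: GenotypePanel,
    pheno: PhenotypeMatrix,
    n_jackknife: int = 50,
) -> SnpEstimate:
    """Haseman-Elston SNP heritability per phenotype.

    Regresses the cross-products z_i * z_j of the standardized phenotype
    on the GRM off-diagonals; the slope estimates h^2_SNP.  Standard
    errors come from a delete-one-block jackknife over samples; with
    fewer than 30 samples the SE is omitted with a warning.
    """
    G = grm(panel.take_samples(list(pheno.data.index)))
    n = G.shape[0]
    iu = np.triu_indices(n, 1)
    g_off = G[iu]
    rows = []
    for col in pheno.data.columns:
        y = pheno.data[col].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        z = np.full(n, np.nan)
        z[ok] = (y[ok] - y[ok].mean()) / y[ok].std(ddof=0)
        cp = z[iu[0]] * z[iu[1]]
        use = ~np.isnan(cp)
        slope = _he_slope(g_off[use], cp[use])
        if n < 30:
            warnings.warn("too few samples for jackknife SE; omitting")
            se = np.nan
        else:
            blocks = np.array_split(np.arange(n), min(n_jackknife, n))
            pseudo = []
            member = np.zeros(n, dtype=int)
            for bi, b in enumerate(blocks):
                member[b] = bi
            pair_block_i = member[iu[0]]
            pair_block_j = member[iu[1]]
            for bi in range(len(blocks)):
                m = use & (pair_block_i != bi) & (pair_block_j != bi)
                pseudo.append(_he_slope(g_off[m], cp[m]))
            pseudo = np.array(pseudo)
            k = len(pseudo)
            se = float(np.sqrt((k - 1) / k * ((pseudo - pseudo.mean()) ** 2).sum()))
        rows.append({"phenotype": col, "h2_snp": slope, "se": se, "n": int(ok.sum())})
    return SnpEstimate(pd.DataFrame(rows).set_index("phenotype"))


def _he_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    return float((x @ (y - y.mean())) / (x @ x))
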