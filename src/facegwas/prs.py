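"""Conditional SNP selection, forward-stepwise multivariable modeling with
R^2 attribution, and polygenic face scores PS = sum_i beta_i * A_i."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, t as t_dist

from .containers import GenotypePanel, PhenotypeMatrix

log = logging.getLogger("facegwas")


def _dosage_matrix(panel: GenotypePanel, variant_ids: list[str], samples) -> np.ndarray:
    vid = {v: j for j, v in enumerate(panel.variants["id"])}
    missing = [v for v in variant_ids if v not in vid]
    if missing:
        raise KeyError(f"variants not in panel: {missing}")
    sid = {s: i for i, s in enumerate(panel.samples)}
    rows = np.array([sid[s] for s in samples])
    cols = np.array([vid[v] for v in variant_ids], dtype=int)
    return panel.dosages[np.ix_(rows, cols)] if len(cols) else np.empty((len(rows), 0))


def _ols_with_pvalue(X: np.ndarray, y: np.ndarray, j: int) -> tuple[float, float]:
    """Beta and two-sided p of column j in an OLS of y on X (with intercept)."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    df = len(y) - Xd.shape[1]
    if df <= 0 or rank < Xd.shape[1]:
        return np.nan, np.nan
    sigma2 = (resid**2).sum() / df
    XtX_inv = np.linalg.pinv(Xd.T @ Xd)
    se = np.sqrt(max(sigma2 * XtX_inv[j + 1, j + 1], 0.0))
    if se == 0:
        return float(beta[j + 1]), 0.0
    tval = beta[j + 1] / se
    return float(beta[j + 1]), float(2.0 * t_dist.sf(abs(tval), df))


def conditional_select(
    panel: GenotypePanel,
    pheno: PhenotypeMatrix,
    lead_variants: list[str],
    candidates: list[str],
    alpha_adj: float = 0.05,
    family: str = "global",
) -> pd.DataFrame:
    """Select candidates with significant effects conditional on the leads.

    Each candidate is regressed on each phenotype with all lead-variant
    dosages as covariates; it is kept when its Bonferroni-adjusted p-value
    is below ``alpha_adj`` for at least one phenotype.  The Bonferroni
    family is candidates x phenotypes (``family='global'``, default) or
    candidates only (``family='per_phenotype'``).  Candidates collinear
    with the leads (conditional R^2 > 0.99) are excluded with a log entry.
    """
    samples = pheno.data.index
    leads = _dosage_matrix(panel, lead_variants, samples)
    rows = []
    kept = []
    n_tests_per_cand = len(pheno.data.columns)
    m = len(candidates) * (n_tests_per_cand if family == "global" else 1)
    for cand in candidates:
        x = _dosage_matrix(panel, [cand], samples)[:, 0]
        ok = ~np.isnan(x) & ~np.isnan(leads).any(axis=1)
        if leads.shape[1]:
            Xl = np.column_stack([np.ones(int(ok.sum())), leads[ok]])
            bh, _, _, _ = np.linalg.lstsq(Xl, x[ok], rcond=None)
            resid = x[ok] - Xl @ bh
            sst = ((x[ok] - x[ok].mean()) ** 2).sum()
            if sst == 0 or 1.0 - (resid**2).sum() / sst > 0.99:
                log.info("conditional_select: %s collinear with leads, excluded", cand)
                continue
        best_p, best_ph, best_beta = np.inf, None, np.nan
        for ph in pheno.data.columns:
            y = pheno.data[ph].to_numpy(dtype=float)
            use = ok & ~np.isnan(y)
            X = np.column_stack([x[use], leads[use]])
            beta, p = _ols_with_pvalue(X, y[use], 0)
            if np.isfinite(p) and p < best_p:
                best_p, best_ph, best_beta = p, ph, beta
        p_adj = min(1.0, best_p * m)
        selected = p_adj < alpha_adj
        rows.append(
            {"variant": cand, "best_phenotype": best_ph, "beta": best_beta,
             "p": best_p, "p_adjusted": p_adj, "selected": selected}
        )
        if selected:
            kept.append(cand)
    log.info("conditional_select: kept %d of %d candidates", len(kept), len(candidates))
    return pd.DataFrame(
        rows, columns=["variant", "best_phenotype", "beta", "p", "p_adjusted", "selected"]
    )


@dataclass
class PolygenicModel:
    """Per-phenotype multivariable SNP models with R^2 attribution.

    ``table`` has one row per (phenotype, step): the variant added, its
    effect in the final joint model, the incremental R^2 at its step, and
    the running total.  Selection order is deterministic (greedy best
    improvement, ties by variant id).
    """

    table: pd.DataFrame
    total_r2: pd.Series
    effect_alleles: dict[str, str] = field(default_factory=dict)

    def betas(self, phenotype: str) -> pd.Series:
        sub = self.table[self.table["phenotype"] == phenotype]
        return pd.Series(sub["beta"].to_numpy(), index=sub["variant"].to_numpy())


def forward_stepwise(
    panel: GenotypePanel,
    pheno: PhenotypeMatrix,
    selected: list[str],
    alpha_enter: float = 0.05,
) -> PolygenicModel:
    """Greedy forward-stepwise regression per phenotype.

    At each step the variant maximizing model R^2 is added and its
    incremental R^2 recorded; the loop stops when the best addition is not
    nominally significant (p >= ``alpha_enter``) or variants are
    exhausted.  Final betas come from the joint model over the variants
    entered for that phenotype.
    """
    if not selected:
        raise ValueError("no selected variants")
    samples = pheno.data.index
    G = _dosage_matrix(panel, selected, samples)
    ea = dict(zip(panel.variants["id"], panel.variants["ea"]))
    rows = []
    totals = {}
    for ph in pheno.data.columns:
        y = pheno.data[ph].to_numpy(dtype=float)
        ok = ~np.isnan(y) & ~np.isnan(G).any(axis=1)
        yo, Go = y[ok], G[ok]
        in_model: list[int] = []
        r2_prev = 0.0
        while len(in_model) < len(selected):
            best = None
            for j in sorted(set(range(len(selected))) - set(in_model),
                            key=lambda j: selected[j]):
                cols = in_model + [j]
                X = Go[:, cols]
                _, p_new = _ols_with_pvalue(X, yo, len(cols) - 1)
                r2 = _model_r2(X, yo)
                if best is None or r2 > best[1] + 1e-15:
                    best = (j, r2, p_new)
            j, r2, p_new = best
            if not (np.isfinite(p_new) and p_new < alpha_enter):
                break
            rows.append(
                {"phenotype": ph, "step": len(in_model) + 1, "variant": selected[j],
                 "delta_r2": r2 - r2_prev, "r2_total": r2}
            )
            in_model.append(j)
            r2_prev = r2
        if in_model:
            X = np.column_stack([np.ones(len(yo)), Go[:, in_model]])
            beta, _, _, _ = np.linalg.lstsq(X, yo, rcond=None)
            for step_i, j in enumerate(in_model):
                rows[-len(in_model) + step_i]["beta"] = beta[step_i + 1]
        totals[ph] = r2_prev
    table = pd.DataFrame(
        rows, columns=["phenotype", "step", "variant", "beta", "delta_r2", "r2_total"]
    )
    return PolygenicModel(
        table=table, total_r2=pd.Series(totals, name="total_r2"), effect_alleles=ea
    )


def _model_r2(X: np.ndarray, y: np.ndarray) -> float:
    Xd = np.column_stack([np.ones(len(y)), X])
    beta, _, _, _ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    sst = ((y - y.mean()) ** 2).sum()
    return 1.0 - (resid**2).sum() / sst if sst > 0 else 0.0


@dataclass
class ScoreResult:
    scores: pd.DataFrame            # per-sample raw PS per phenotype
    standardized: pd.DataFrame      # z-scored over the evaluation sample
    group_means: pd.DataFrame | None
    anova_p: pd.Series | None
    n_imputed: int


def score(
    panel: GenotypePanel,
    model: PolygenicModel,
    groups: pd.Series | None = None,
    standardize: str = "pooled",
) -> ScoreResult:
    """Polygenic scores PS = sum_i beta_i * A_i per sample and phenotype.

    Missing dosages are mean-imputed (count reported); a sample with all
    model variants missing scores NaN.  Standardization is over the scored
    sample (``pooled``, default) or within each group (``per_group``).
    When group labels are given, per-group means and a one-way ANOVA
    p-value (H0: equal mean PS in all groups) are reported per phenotype.
    """
    phenos = list(dict.fromkeys(model.table["phenotype"]))
    raw = {}
    n_imputed = 0
    for ph in phenos:
        betas = model.betas(ph)
        if betas.empty:
            continue
        G = _dosage_matrix(panel, list(betas.index), panel.samples)
        miss = np.isnan(G)
        all_missing = miss.all(axis=1)
        n_imputed += int(miss[~all_missing].sum())
        mu = np.nanmean(G, axis=0)
        Gf = np.where(miss, mu, G)
        ps = Gf @ betas.to_numpy()
        ps[all_missing] = np.nan
        raw[ph] = ps
    scores = pd.DataFrame(raw, index=pd.Index(panel.samples, name="sample"))
    if standardize == "per_group" and groups is not None:
        std = scores.copy()
        for g in groups.unique():
            sel = groups.loc[scores.index] == g
            std.loc[sel] = (scores.loc[sel] - scores.loc[sel].mean()) / scores.loc[sel].std(ddof=0)
    else:
        std = (scores - scores.mean()) / scores.std(ddof=0)
    group_means = anova = None
    if groups is not None:
        g = groups.loc[scores.index]
        group_means = std.groupby(g).mean()
        anova = {}
        for ph in std.columns:
            arrays = [std.loc[g == lvl, ph].dropna() for lvl in g.unique()]
            arrays = [a for a in arrays if len(a) > 1]
            anova[ph] = f_oneway(*arrays).pvalue if len(arrays) > 1 else np.nan
        anova = pd.Series(anova, name="anova_p")
    return ScoreResult(scores, std, group_means, anova, n_imputed)
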