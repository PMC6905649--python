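"""Population-differentiation and haplotype-based selection statistics.

FST follows the Weir-Cockerham (1984) variance-components estimator on
genotype counts; EHH is the probability that two randomly drawn
haplotypes from an allele class are identical from the core variant out
to a position, and iHS is the log-ratio of the EHH integrals (over
physical distance, in bp) on the ancestral versus derived backgrounds,
standardized within 0.05-wide derived-allele-frequency bins.  Empirical
significance uses top-1% cutoffs over all scanned variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypePanel

log = logging.getLogger("facegwas")


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def weir_cockerham_fst(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> np.ndarray:
    """Per-variant Weir-Cockerham FST from per-population summaries.

    Parameters are arrays of shape (r, m) for r populations and m
    variants: sample counts ``n``, allele frequencies ``p``, and observed
    heterozygote proportions ``h``.  Returns a/(a+b+c); variants
    monomorphic in all populations (a+b+c = 0) come back NaN.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = n.shape[0]
    nbar = n.mean(axis=0)
    nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n * p).sum(axis=0) / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / (r * nbar)
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(np.abs(denom) > 0, a / denom, np.nan)
    return fst


def fst_scan(
    panel: GenotypePanel, populations: pd.Series, pair: tuple[str, str]
) -> tuple[pd.DataFrame, float]:
    """Per-variant FST for one population pair, plus the empirical
    99th-percentile cutoff over all scanned variants.

    Variants monomorphic in both populations are excluded (FST
    undefined).  Each population needs at least 2 genotyped samples.
    """
    pops = populations.loc[panel.samples]
    stats = []
    for label in pair:
        rows = np.flatnonzero((pops == label).to_numpy())
        if rows.size < 2:
            raise ValueError(f"population {label!r} has fewer than 2 samples")
        g = panel.dosages[rows]
        called = ~np.isnan(g)
        n_i = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            p_i = np.nansum(g, axis=0) / (2 * n_i)
        het = np.nansum(np.round(g) == 1, axis=0) / np.maximum(n_i, 1)
        stats.append((n_i, p_i, het))
    n = np.vstack([s[0] for s in stats])
    p = np.vstack([s[1] for s in stats])
    h = np.vstack([s[2] for s in stats])
    fst = weir_cockerham_fst(n, p, h)
    out = panel.variants[["id", "chrom", "pos"]].copy()
    out["fst"] = fst
    out = out[np.isfinite(fst)].reset_index(drop=True)
    cutoff = float(np.percentile(out["fst"], 99)) if len(out) else np.nan
    log.info("fst_scan %s-%s: %d variants, top-1%% cutoff %.4f", *pair, len(out), cutoff)
    return out, cutoff


# ---------------------------------------------------------------------------
# EHH
# ---------------------------------------------------------------------------

def _homozygosity(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    n = labels.size
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core: int,
    hap_subset: np.ndarray,
    direction: int = 1,
) -> pd.DataFrame:
    """Extended haplotype homozygosity away from a core variant.

    ``hap_subset`` indexes the haplotypes of one allele class at the core;
    EHH(x) is the fraction of haplotype pairs in that class identical at
    every variant from the core out to x.  The curve starts at 1 at the
    core and is non-increasing.  Requires at least 2 haplotypes.
    """
    if hap_subset.size < 2:
        raise ValueError("EHH needs at least 2 haplotypes in the allele class")
    H = haplotypes[hap_subset]
    step = 1 if direction >= 0 else -1
    out_pos = [int(positions[core])]
    out_ehh = [1.0]
    labels = np.zeros(H.shape[0], dtype=np.int64)
    j = core + step
    while 0 <= j < haplotypes.shape[1]:
        _, labels = np.unique(labels * 4 + H[:, j], return_inverse=True)
        out_pos.append(int(positions[j]))
        out_ehh.append(_homozygosity(labels))
        j += step
    return pd.DataFrame({"pos": out_pos, "ehh": out_ehh})


# ---------------------------------------------------------------------------
# iHS
# ---------------------------------------------------------------------------

def _ihh_one_side(H, positions, core, cutoff, gap_limit, step):
    """Trapezoid integral of EHH over bp in one direction.

    Integration stops at the linearly interpolated crossing of the EHH
    cutoff; a gap larger than ``gap_limit`` truncates the integral there.
    Returns (area, reached_cutoff).
    """
    labels = np.zeros(H.shape[0], dtype=np.int64)
    prev_pos = float(positions[core])
    prev_ehh = 1.0
    area = 0.0
    j = core + step
    while 0 <= j < len(positions):
        gap = abs(float(positions[j]) - prev_pos)
        if gap > gap_limit:
            return area, True
        _, labels = np.unique(labels * 4 + H[:, j], return_inverse=True)
        e = _homozygosity(labels)
        if e < cutoff:
            frac = (prev_ehh - cutoff) / (prev_ehh - e)
            area += 0.5 * (prev_ehh + cutoff) * gap * frac
            return area, True
        area += 0.5 * (prev_ehh + e) * gap
        prev_pos, prev_ehh = float(positions[j]), e
        j += step
    return area, False  # hit the region edge with EHH still above cutoff


@dataclass
class SelectionScan:
    """Per-variant iHS results with the empirical |iHS| cutoff.

    ``bin_stats`` holds the per-frequency-bin mean and sd of the
    unstandardized scores used for standardization, so a genome-wide
    (neutral) scan can serve as the reference distribution for a focal
    region.
    """

    table: pd.DataFrame
    cutoff: float
    bin_stats: pd.DataFrame


def ihs(
    panel: GenotypePanel,
    maf_range: tuple[float, float] = (0.05, 0.95),
    ehh_cutoff: float = 0.05,
    gap_limit_bp: float = 200_000.0,
    bin_width: float = 0.05,
    reference: SelectionScan | None = None,
) -> SelectionScan:
    """Integrated haplotype score for every eligible variant of a phased
    panel with ancestral-allele annotation.

    For each variant the EHH decay is integrated (trapezoid, physical
    distance) separately on the derived and ancestral backgrounds, both
    directions summed, until EHH drops below ``ehh_cutoff``.  The
    unstandardized score is ln(iHH_ancestral / iHH_derived); scores are
    standardized to mean 0, sd 1 within ``bin_width``-wide derived-allele
    frequency bins.  Variants whose EHH never reaches the cutoff before
    the region edge are flagged edge-truncated and excluded from
    standardization; so are variants with derived frequency outside
    ``maf_range``.  The reported cutoff is the top-1% of |standardized
    iHS|.

    When ``reference`` is given (e.g. a genome-wide scan of putatively
    neutral variants), its per-bin means/sds standardize this panel's
    scores and its empirical cutoff is carried over - the usual way a
    focal region is judged against a genome-wide null distribution.
    """
    if not panel.phased:
        raise ValueError("iHS requires phased haplotypes")
    if "aa" not in panel.variants.columns or panel.variants["aa"].isna().any():
        raise ValueError("iHS requires ancestral-allele annotation for every variant")
    H = panel.haplotypes
    positions = panel.variants["pos"].to_numpy()
    # derived allele indicator per haplotype: ancestral equals EA or OA
    anc_is_ea = (panel.variants["aa"] == panel.variants["ea"]).to_numpy()
    rows = []
    for j in range(panel.n_variants):
        hap = H[:, j]
        valid = hap >= 0
        derived = (hap == 0) if anc_is_ea[j] else (hap == 1)
        daf = float(derived[valid].mean()) if valid.any() else np.nan
        row = {"id": panel.variants["id"].iloc[j], "pos": int(positions[j]),
               "daf": daf, "uihs": np.nan, "edge_truncated": False}
        if not (maf_range[0] <= daf <= maf_range[1]):
            rows.append(row)
            continue
        d_idx = np.flatnonzero(derived & valid)
        a_idx = np.flatnonzero(~derived & valid)
        if d_idx.size < 2 or a_idx.size < 2:
            rows.append(row)
            continue
        edge = False
        ihh = {}
        for name, idx in (("D", d_idx), ("A", a_idx)):
            Hc = H[idx]
            total = 0.0
            for step in (-1, 1):
                area, closed = _ihh_one_side(Hc, positions, j, ehh_cutoff, gap_limit_bp, step)
                total += area
                edge |= not closed
            ihh[name] = total
        if ihh["D"] > 0 and ihh["A"] > 0:
            row["uihs"] = float(np.log(ihh["A"] / ihh["D"]))
        row["edge_truncated"] = edge
        rows.append(row)
    table = pd.DataFrame(rows)
    table["bin"] = np.floor(table["daf"] / bin_width).astype("Int64")
    table["ihs"] = np.nan
    usable = table["uihs"].notna() & ~table["edge_truncated"]
    if reference is None:
        bin_rows = []
        for b, grp in table[usable].groupby("bin"):
            mu = grp["uihs"].mean()
            sd = grp["uihs"].std(ddof=0)
            bin_rows.append({"bin": int(b), "mean": mu, "sd": sd, "n": len(grp)})
            if sd > 0:
                table.loc[grp.index, "ihs"] = (grp["uihs"] - mu) / sd
        bin_stats = pd.DataFrame(bin_rows, columns=["bin", "mean", "sd", "n"])
    else:
        bin_stats = reference.bin_stats
        stats_by_bin = bin_stats.set_index("bin")
        for b, grp in table[usable].groupby("bin"):
            if int(b) not in stats_by_bin.index:
                continue
            mu, sd = stats_by_bin.loc[int(b), ["mean", "sd"]]
            if sd > 0:
                table.loc[grp.index, "ihs"] = (grp["uihs"] - mu) / sd
    scored = table["ihs"].abs().dropna()
    if reference is not None:
        cutoff = reference.cutoff
    else:
        cutoff = float(np.percentile(scored, 99)) if len(scored) else np.nan
    table["percentile"] = table["ihs"].abs().rank(pct=True) * 100
    log.info("ihs: %d variants scored, top-1%% |iHS| cutoff %.3f", int(scored.size), cutoff)
    return SelectionScan(table=table, cutoff=cutoff, bin_stats=bin_stats)
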