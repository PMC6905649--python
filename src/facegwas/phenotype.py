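"""Landmark phenotyping: Procrustes alignment, distance phenotypes,
outlier masking, normality checks, covariate adjustment, and the
phenotype correlation/clustering structure."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import shapiro

from .containers import AlignedShapes, LandmarkSet, PhenotypeMatrix
from .registry import DISTANCE_PAIRS, distance_name

log = logging.getLogger("facegwas")


# ---------------------------------------------------------------------------
# generalized Procrustes analysis
# ---------------------------------------------------------------------------

def _center_and_scale(X: np.ndarray) -> tuple[np.ndarray, float]:
    """Center a configuration at the origin and scale to unit centroid size."""
    Xc = X - X.mean(axis=0)
    size = np.sqrt((Xc**2).sum())
    return Xc / size if size > 0 else Xc, size


def _rotate_to(X: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation of X onto target (no reflection)."""
    U, _, Vt = np.linalg.svd(target.T @ X)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] = -U[:, -1]
        R = U @ Vt
    return X @ R.T


def gpa_align(shapes: LandmarkSet, tol: float = 1e-10, max_iter: int = 100) -> AlignedShapes:
    """Generalized Procrustes superimposition of complete configurations.

    Iteratively centers each configuration, scales it to unit centroid
    size, rotates it to the current consensus by orthogonal Procrustes
    (reflections disallowed), and updates the consensus until its change
    drops below *tol*.  The initial consensus is the mean of the centered,
    scaled configurations, so the result does not depend on sample order.
    Incomplete configurations are excluded; all-coincident (zero centroid
    size) configurations are an error.
    """
    complete = shapes.complete_subset()
    if complete.n_samples < 2:
        raise ValueError("GPA needs at least 2 complete configurations")
    n, p, _ = complete.coords.shape
    scaled = np.empty_like(complete.coords)
    sizes = np.empty(n)
    for i in range(n):
        s, size = _center_and_scale(complete.coords[i])
        if size <= 1e-12:
            raise ValueError(f"degenerate (all-coincident) configuration for sample "
                             f"{complete.samples[i]!r}")
        scaled[i], sizes[i] = s, size

    consensus, _ = _center_and_scale(scaled.mean(axis=0))
    aligned = scaled.copy()
    residual = np.inf
    for it in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = _rotate_to(scaled[i], consensus)
        new_consensus, _ = _center_and_scale(aligned.mean(axis=0))
        residual = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
        consensus = new_consensus
        if residual < tol:
            break
    log.info("gpa_align: %d configurations, %d iterations, residual %.3g", n, it, residual)
    return AlignedShapes(
        consensus=consensus,
        aligned=aligned,
        centroid_sizes=sizes,
        samples=list(complete.samples),
        iterations=it,
        residual=residual,
        landmark_names=complete.landmark_names,
    )


# ---------------------------------------------------------------------------
# distance phenotypes
# ---------------------------------------------------------------------------

def pairwise_distances(aligned: AlignedShapes, restore_size: bool = True) -> PhenotypeMatrix:
    """All C(p, 2) pairwise Euclidean distances of the aligned shapes.

    With ``restore_size`` the unit-size aligned shapes are multiplied by
    the mean pre-scaling centroid size, putting distances back on the
    original coordinate units (averaged over the sample); otherwise they
    are on the unit-centroid-size shape scale.
    """
    names = aligned.landmark_names
    pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
    cols = [distance_name(names[i], names[j]) for i, j in pairs]
    i_idx = np.array([p[0] for p in pairs])
    j_idx = np.array([p[1] for p in pairs])
    diffs = aligned.aligned[:, i_idx, :] - aligned.aligned[:, j_idx, :]
    d = np.sqrt((diffs**2).sum(axis=2))
    if restore_size:
        d = d * aligned.centroid_sizes.mean()
    return PhenotypeMatrix(pd.DataFrame(d, index=aligned.samples, columns=cols), state="raw")


def mask_outliers(pheno: PhenotypeMatrix, k_sd: float = 3.0) -> PhenotypeMatrix:
    """Mask values more than ``k_sd`` standard deviations from the column
    mean (single pass; mean/sd from non-missing values of that column).

    Columns with fewer than 3 non-missing values are left untouched with a
    warning.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    out = pheno.data.copy()
    n_masked = 0
    for col in out.columns:
        x = out[col]
        ok = x.notna()
        if ok.sum() < 3:
            warnings.warn(f"phenotype {col!r} has <3 non-missing values; not masked")
            continue
        mu, sd = x[ok].mean(), x[ok].std(ddof=1)
        if sd == 0:
            continue
        bad = ok & ((x - mu).abs() > k_sd * sd)
        n_masked += int(bad.sum())
        out.loc[bad, col] = np.nan
    log.info("mask_outliers: masked %d cells at |z| > %g", n_masked, k_sd)
    return PhenotypeMatrix(out, state="outlier-masked")


def check_normality(pheno: PhenotypeMatrix) -> pd.DataFrame:
    """Shapiro-Wilk W and p per phenotype (reporting only, no filtering)."""
    rows = []
    for col in pheno.data.columns:
        x = pheno.data[col].dropna().to_numpy()
        if len(x) < 3 or np.ptp(x) == 0:
            rows.append({"phenotype": col, "W": np.nan, "p": np.nan, "n": len(x)})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W, p = shapiro(x)
        rows.append({"phenotype": col, "W": W, "p": p, "n": len(x)})
    return pd.DataFrame(rows).set_index("phenotype")


# ---------------------------------------------------------------------------
# covariate adjustment
# ---------------------------------------------------------------------------

@dataclass
class AdjustmentResult:
    adjusted: PhenotypeMatrix
    effects: pd.DataFrame     # per (phenotype, covariate): beta, se, t, p
    r_squared: pd.Series      # per phenotype


def _design_matrix(covariates: pd.DataFrame, columns: list[str]) -> np.ndarray:
    X = covariates[columns].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(X)), X])


def adjust_covariates(
    pheno: PhenotypeMatrix,
    covariates: pd.DataFrame,
    columns: list[str] | None = None,
) -> AdjustmentResult:
    """Regress each phenotype on the covariates; keep the residuals.

    The adjusted phenotype is the complete-case OLS residual (mean zero by
    construction).  Per-covariate effect estimates, t-test p-values, and
    the model R^2 are reported.  A rank-deficient design is an error
    naming the collinear columns.
    """
    if columns is None:
        columns = [c for c in ("sex", "age") if c in covariates.columns]
        columns += [c for c in covariates.columns if c.startswith("PC")]
    cov = covariates.loc[pheno.data.index, columns]
    X_full = _design_matrix(cov, columns)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        collinear = [
            c for i, c in enumerate(columns)
            if np.linalg.matrix_rank(np.delete(X_full, i + 1, axis=1)) ==
            np.linalg.matrix_rank(X_full)
        ]
        raise ValueError(f"rank-deficient covariate design; collinear columns: {collinear}")

    out = pd.DataFrame(np.nan, index=pheno.data.index, columns=pheno.data.columns)
    eff_rows = []
    r2 = {}
    for col in pheno.data.columns:
        y = pheno.data[col].to_numpy(dtype=float)
        ok = ~(np.isnan(y) | np.isnan(X_full).any(axis=1))
        Xo, yo = X_full[ok], y[ok]
        if len(yo) <= X_full.shape[1]:
            r2[col] = np.nan
            continue
        beta, _, _, _ = np.linalg.lstsq(Xo, yo, rcond=None)
        fitted = Xo @ beta
        resid = yo - fitted
        sst = ((yo - yo.mean()) ** 2).sum()
        sse = (resid**2).sum()
        r2[col] = 1.0 - sse / sst if sst > 0 else np.nan
        df = len(yo) - X_full.shape[1]
        sigma2 = sse / df if df > 0 else np.nan
        XtX_inv = np.linalg.pinv(Xo.T @ Xo)
        se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
        from scipy.stats import t as t_dist

        for ci, cname in enumerate(columns):
            b, s = beta[ci + 1], se[ci + 1]
            tval = b / s if s > 0 else np.nan
            p = 2.0 * t_dist.sf(abs(tval), df) if np.isfinite(tval) else np.nan
            eff_rows.append(
                {"phenotype": col, "covariate": cname, "beta": b, "se": s, "t": tval, "p": p}
            )
        out.loc[ok, col] = resid
    effects = pd.DataFrame(eff_rows, columns=["phenotype", "covariate", "beta", "se", "t", "p"])
    return AdjustmentResult(
        adjusted=PhenotypeMatrix(out, state="covariate-adjusted"),
        effects=effects,
        r_squared=pd.Series(r2, name="r_squared"),
    )


# ---------------------------------------------------------------------------
# correlation structure
# ---------------------------------------------------------------------------

@dataclass
class CorrelationStructure:
    correlations: pd.DataFrame
    linkage: np.ndarray          # scipy linkage matrix on 1 - |r|
    labels: list[str]
    excluded: list[str]

    def to_newick(self) -> str:
        """Serialize the merge tree as Newick with merge-height branch lengths."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        newick = {i: self.labels[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = h - heights[a]
            lb = h - heights[b]
            node = n + k
            newick[node] = f"({newick[a]}:{la:.6g},{newick[b]}:{lb:.6g})"
            heights[node] = h
        return newick[n + len(self.linkage) - 1] + ";"


def correlation_structure(
    pheno: PhenotypeMatrix, method: str = "average"
) -> CorrelationStructure:
    """Pairwise-complete Pearson correlations and agglomerative clustering.

    The dissimilarity is 1 - |r|; merges follow the Lance-Williams
    recurrence with the chosen linkage (average by default).  Phenotypes
    with zero variance are excluded with a warning.
    """
    data = pheno.data
    variances = data.var(skipna=True)
    excluded = [c for c in data.columns if not variances[c] > 0]
    if excluded:
        warnings.warn(f"excluding zero-variance phenotypes: {excluded}")
        data = data.drop(columns=excluded)
    if data.shape[1] < 2:
        raise ValueError("need at least 2 phenotypes with variance")
    corr = data.corr(method="pearson", min_periods=2)
    D = 1.0 - corr.abs().to_numpy()
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = linkage(squareform(D, checks=False), method=method)
    return CorrelationStructure(
        correlations=corr, linkage=Z, labels=list(data.columns), excluded=excluded
    )
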