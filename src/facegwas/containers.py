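"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .registry import LANDMARK_NAMES, N_LANDMARKS

#: Required columns of a summary-statistics table.
SUMMARY_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "PHENOTYPE", "BETA", "SE", "P", "N"]


@dataclass
class GenotypePanel:
    """Samples x variants dosage matrix with variant metadata.

    Attributes
    ----------
    dosages : ndarray, shape (n_samples, n_variants)
        Effect-allele dosages in [0, 2]; missing entries are NaN.
    variants : pandas.DataFrame
        One row per variant with columns ``id, chrom, pos, ea, oa`` and
        optionally ``aa`` (ancestral allele) and ``info`` (imputation
        quality).  Positions are 1-based; row order is file order.
    samples : list of str
    haplotypes : ndarray of int8, shape (2 * n_samples, n_variants), optional
        Phased haplotypes coded 0/1 (effect allele = 1); -1 for missing.
        Haplotypes 2i and 2i+1 belong to sample i.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def phased(self) -> bool:
        return self.haplotypes is not None

    def allele_freq(self) -> np.ndarray:
        """Effect-allele frequency per variant, ignoring missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def take_variants(self, mask_or_idx) -> "GenotypePanel":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        haps = self.haplotypes[:, idx] if self.haplotypes is not None else None
        return GenotypePanel(
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            haplotypes=haps,
        )

    def take_samples(self, keep: list[str]) -> "GenotypePanel":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([pos[s] for s in keep], dtype=int)
        haps = None
        if self.haplotypes is not None:
            hidx = np.column_stack([2 * idx, 2 * idx + 1]).ravel()
            haps = self.haplotypes[hidx]
        return GenotypePanel(self.dosages[idx], self.variants, list(keep), haps)


@dataclass
class LandmarkSet:
    """Per-sample 13-landmark 3D configurations.

    ``coords`` is (n_samples, 13, 3) with NaN rows for unplaced landmarks;
    ``complete`` flags samples with all 13 landmarks present.
    """

    coords: np.ndarray
    samples: list[str]
    landmark_names: tuple[str, ...] = LANDMARK_NAMES

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape[1:] != (len(self.landmark_names), 3):
            raise ValueError(f"coords must be (n, {len(self.landmark_names)}, 3)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def complete(self) -> np.ndarray:
        return ~np.isnan(self.coords).any(axis=(1, 2))

    def complete_subset(self) -> "LandmarkSet":
        keep = self.complete
        return LandmarkSet(
            self.coords[keep],
            [s for s, k in zip(self.samples, keep) if k],
            self.landmark_names,
        )


@dataclass
class AlignedShapes:
    """Result of generalized Procrustes superimposition.

    The consensus is centered at the origin with unit centroid size; each
    aligned configuration likewise has unit centroid size.  ``centroid_sizes``
    holds the pre-scaling centroid size of each configuration, so distances
    can be restored to the original unit scale.
    """

    consensus: np.ndarray
    aligned: np.ndarray
    centroid_sizes: np.ndarray
    samples: list[str]
    iterations: int
    residual: float
    landmark_names: tuple[str, ...] = LANDMARK_NAMES


@dataclass
class PhenotypeMatrix:
    """Samples x named distance phenotypes, with missingness as NaN.

    ``state`` tracks the adjustment stage: ``raw`` -> ``outlier-masked`` ->
    ``covariate-adjusted``.
    """

    data: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def phenotypes(self) -> list[str]:
        return list(self.data.columns)

    def copy(self, state: str | None = None) -> "PhenotypeMatrix":
        return PhenotypeMatrix(self.data.copy(), state or self.state)


@dataclass
class EffectiveTestCount:
    """Effective number of independent traits from a correlation spectrum."""

    eigenvalues: np.ndarray
    meff: float
    method: str

    @property
    def meff_int(self) -> int:
        """Integer count used for Bonferroni thresholding (floored)."""
        return int(np.floor(self.meff + 1e-9))

    def threshold(self, alpha_gw: float) -> float:
        return alpha_gw / self.meff_int


@dataclass
class CombinedTestResult:
    """Scaled chi-squared combination of k dependent -2 log p statistics."""

    statistic: float          # T = sum of -2 log P_i
    k: int
    expectation: float        # E = 2k
    variance: float           # V = 4k + 2 sum cov
    scale: float              # c = V / (2E)
    dof: float                # f = 2 E^2 / V
    p_value: float
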