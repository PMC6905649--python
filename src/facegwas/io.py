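"""Readers and writers for the pipeline's file formats.

Genotypes are read from VCF (via cyvcf2) or from a plain dosage TSV;
landmarks, covariates, phenotypes and summary statistics travel as TSV.
Every reader/writer pair is a lossless round trip at the stated precision.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import SUMMARY_COLUMNS, GenotypePanel, LandmarkSet
from .registry import LANDMARK_NAMES

log = logging.getLogger("facegwas")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, split_multiallelic: bool = False) -> GenotypePanel:
    """Read a genotype panel from VCF or dosage TSV.

    VCF positions are kept 1-based and variant order follows file order.
    The effect allele is ALT; the ancestral allele is taken from the ``AA``
    INFO key when present.  If every genotype is phased, haplotypes are
    retained so that downstream haplotype statistics (EHH, iHS) can run.

    Multiallelic records are rejected unless ``split_multiallelic`` is set,
    in which case each ALT becomes its own biallelic variant with genotypes
    carrying other ALTs treated as missing.
    """
    path = Path(path)
    if path.suffix in (".tsv", ".txt") or path.name.endswith(".dosage.tsv"):
        return _read_dosage_tsv(path)
    return _read_vcf(path, split_multiallelic)


def _read_vcf(path: Path, split_multiallelic: bool) -> GenotypePanel:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    dosage_cols: list[np.ndarray] = []
    hap_cols: list[np.ndarray] = []
    meta: list[dict] = []
    all_phased = True
    for rec_i, var in enumerate(vcf):
        alts = var.ALT
        if len(alts) != 1:
            if not split_multiallelic:
                raise ValueError(
                    f"multiallelic record at {var.CHROM}:{var.POS} (record {rec_i + 1}); "
                    "pass split_multiallelic=True to split into biallelic variants"
                )
        gts = np.array([g[:2] for g in var.genotypes], dtype=int)  # (n, 2)
        phased = all(g[2] for g in var.genotypes)
        all_phased &= phased
        aa = var.INFO.get("AA")
        info = var.INFO.get("INFO")
        for alt_i, alt in enumerate(alts, start=1):
            alt_hap = (gts == alt_i).astype(np.int8)
            other_alt = (gts > 0) & (gts != alt_i)
            missing = (gts < 0) | other_alt
            haps = np.where(missing, np.int8(-1), alt_hap).reshape(-1)
            dos = alt_hap[:, 0] + alt_hap[:, 1]
            dos = np.where(missing.any(axis=1), np.nan, dos.astype(float))
            dosage_cols.append(dos)
            hap_cols.append(haps)
            meta.append(
                {
                    "id": var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{alt}",
                    "chrom": var.CHROM,
                    "pos": var.POS,
                    "ea": alt,
                    "oa": var.REF,
                    "aa": aa,
                    "info": info,
                }
            )
    variants = pd.DataFrame(meta, columns=["id", "chrom", "pos", "ea", "oa", "aa", "info"])
    dosages = (
        np.column_stack(dosage_cols) if dosage_cols else np.empty((n, 0))
    )
    haplotypes = None
    if all_phased and hap_cols:
        haplotypes = np.column_stack(hap_cols)
    log.info("read_genotypes: %d samples, %d variants from %s", n, len(variants), path)
    return GenotypePanel(dosages, variants, samples, haplotypes)


_DOSAGE_META = ["id", "chrom", "pos", "ea", "oa", "aa"]


def write_dosage_tsv(panel: GenotypePanel, path: str | Path) -> None:
    """Write a panel as a dosage TSV (variants as rows, samples as columns)."""
    meta = panel.variants.reindex(columns=_DOSAGE_META)
    body = pd.DataFrame(
        panel.dosages.T, columns=panel.samples, index=meta.index
    )
    pd.concat([meta, body], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def _read_dosage_tsv(path: Path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing_cols = [c for c in _DOSAGE_META if c not in df.columns]
    if missing_cols:
        raise ValueError(f"dosage TSV {path} lacks columns {missing_cols}")
    samples = [c for c in df.columns if c not in _DOSAGE_META]
    dosages = df[samples].to_numpy(dtype=float).T
    bad = np.flatnonzero((dosages < 0) | (dosages > 2))
    if bad.size:
        row = bad[0] % len(df)
        raise ValueError(f"dosage out of [0, 2] at data line {row + 2} of {path}")
    variants = df[_DOSAGE_META].copy()
    return GenotypePanel(dosages, variants, samples)


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write a biallelic VCF (phased GT if haplotypes are present)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(panel.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        sep = "|" if panel.phased else "/"
        for j, var in panel.variants.iterrows():
            aa = var.get("aa")
            info = f"AA={aa}" if isinstance(aa, str) else "."
            if panel.phased:
                h = panel.haplotypes[:, j]
                gts = [
                    f"{_gt(h[2 * i])}{sep}{_gt(h[2 * i + 1])}"
                    for i in range(len(panel.samples))
                ]
            else:
                gts = []
                for d in panel.dosages[:, j]:
                    if np.isnan(d):
                        gts.append("./.")
                    else:
                        k = int(round(d))
                        gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[k])
            fh.write(
                f"{var['chrom']}\t{var['pos']}\t{var['id']}\t{var['oa']}\t{var['ea']}"
                f"\t.\t.\t{info}\tGT\t" + "\t".join(gts) + "\n"
            )


def _gt(h: int) -> str:
    return "." if h < 0 else str(int(h))


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read per-sample landmark coordinates from TSV.

    Expects columns ``sample, landmark, x, y, z``; unknown landmark names
    are rejected, duplicate (sample, landmark) rows are an error, and
    samples missing any of the 13 landmarks are flagged incomplete (their
    missing rows become NaN).  Row order does not matter.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "landmark", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"landmark TSV needs columns {sorted(required)}")
    unknown = set(df["landmark"]) - set(LANDMARK_NAMES)
    if unknown:
        raise ValueError(f"unknown landmark names: {sorted(unknown)}")
    dup = df.duplicated(subset=["sample", "landmark"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate row for sample {row['sample']!r} landmark {row['landmark']!r}"
        )
    samples = sorted(df["sample"].astype(str).unique())
    lm_idx = {name: i for i, name in enumerate(LANDMARK_NAMES)}
    coords = np.full((len(samples), len(LANDMARK_NAMES), 3), np.nan)
    s_idx = {s: i for i, s in enumerate(samples)}
    si = df["sample"].astype(str).map(s_idx).to_numpy()
    li = df["landmark"].map(lm_idx).to_numpy()
    coords[si, li] = df[["x", "y", "z"]].to_numpy(dtype=float)
    return LandmarkSet(coords, samples)


def write_landmarks(lms: LandmarkSet, path: str | Path) -> None:
    rows = []
    for i, s in enumerate(lms.samples):
        for j, name in enumerate(lms.landmark_names):
            xyz = lms.coords[i, j]
            if not np.isnan(xyz).any():
                rows.append((s, name, *xyz))
    pd.DataFrame(rows, columns=["sample", "landmark", "x", "y", "z"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# summary statistics / tables
# ---------------------------------------------------------------------------

def write_summary_stats(stats: pd.DataFrame, path: str | Path) -> None:
    """Write an association/meta summary table.

    Required columns: SNP CHR POS EA OA EAF PHENOTYPE BETA SE P N.  Betas
    are on the effect-allele dosage scale; extra columns (Q, Q_P, ...) are
    preserved.  An empty table produces a header-only file.
    """
    missing = [c for c in SUMMARY_COLUMNS if c not in stats.columns]
    if missing:
        raise ValueError(f"summary stats lack columns {missing}")
    ordered = SUMMARY_COLUMNS + [c for c in stats.columns if c not in SUMMARY_COLUMNS]
    stats[ordered].to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "SNP": str, "PHENOTYPE": str})
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary stats file {path} lacks columns {missing}")
    return df


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read a sample covariate table indexed by sample id."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "sample" not in df.columns:
        raise ValueError("covariate TSV needs a 'sample' column")
    return df.set_index("sample")


def write_phenotypes(data: pd.DataFrame, path: str | Path) -> None:
    data.to_csv(path, sep="\t", index_label="sample", na_rep="NA", float_format="%.10g")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")
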