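"""Variant QC (HWE exact test), genotype PCs, and the additive-model
association scan against closed-form oracles and null calibration."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import t as t_dist

import facegwas as fg
from facegwas.association import CHI2_1_MEDIAN, hwe_exact_p
from facegwas.config import RunConfig
from facegwas.containers import GenotypePanel, PhenotypeMatrix
from facegwas.simulate import PopulationSpec, SimSpec, simulate_haplotypes


def _panel(dosages, pos=None):
    n, m = dosages.shape
    variants = pd.DataFrame({
        "id": [f"v{j}" for j in range(m)], "chrom": "1",
        "pos": pos if pos is not None else np.arange(1, m + 1) * 100,
        "ea": "A", "oa": "G",
    })
    return GenotypePanel(np.asarray(dosages, dtype=float), variants,
                         [f"s{i}" for i in range(n)])


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def _hwe_oracle(n_aa, n_ab, n_bb):
    """Brute-force enumeration of the conditional genotype distribution."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    probs = {}
    for ab in range(min(na, 2 * n - na) + 1):
        if (na - ab) % 2:
            continue
        aa = (na - ab) // 2
        bb = n - aa - ab
        if bb < 0:
            continue
        logp = (
            math.lgamma(n + 1) - math.lgamma(aa + 1) - math.lgamma(ab + 1)
            - math.lgamma(bb + 1) + ab * math.log(2)
            - (math.lgamma(2 * n + 1) - math.lgamma(na + 1) - math.lgamma(2 * n - na + 1))
        )
        probs[ab] = math.exp(logp)
    total = sum(probs.values())
    p_obs = probs[n_ab] / total
    return sum(p / total for p in probs.values() if p / total <= p_obs * (1 + 1e-12))


@pytest.mark.parametrize("counts", [
    (1469, 138, 5),
    (10, 10, 10),
    (50, 0, 50),
    (0, 100, 0),
    (20, 40, 20),
])
def test_hwe_exact_matches_enumeration_oracle(counts):
    assert hwe_exact_p(*counts) == pytest.approx(_hwe_oracle(*counts), rel=1e-10)


def test_hwe_threshold_decision():
    """QC removal decisions are consistent with the exact-test p-value:
    (1469, 138, 5) is close to equilibrium and passes a 1e-4 filter; a
    strongly heterozygote-deficient variant fails it."""
    p_near = hwe_exact_p(1469, 138, 5)
    assert p_near == pytest.approx(_hwe_oracle(1469, 138, 5), rel=1e-10)
    assert p_near > 1e-4
    p_deficit = hwe_exact_p(1400, 0, 100)
    assert p_deficit < 1e-4
    cfg = RunConfig()
    g = np.array([[0.0] * 1469 + [1.0] * 138 + [2.0] * 5,
                  [0.0] * 1400 + [1.0] * 0 + [2.0] * 100 + [0.0] * 112]).T
    panel = _panel(g)
    kept, report = fg.variant_qc(panel, cfg)
    assert report.n_removed_hwe == 1
    assert list(kept.variants["id"]) == ["v0"]


def test_variant_qc_thresholds():
    rng = np.random.default_rng(0)
    n = 400
    good = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
    rare = rng.binomial(2, 0.005, size=(n, 1)).astype(float)   # MAF < 0.01
    sparse = good.copy()
    sparse[: int(0.2 * n)] = np.nan                            # call rate 0.8
    panel = _panel(np.hstack([good, rare, sparse]))
    kept, report = fg.variant_qc(panel, RunConfig())
    assert report.n_input == 3
    assert report.n_removed_maf >= 1
    assert report.n_removed_call_rate == 1
    assert list(kept.variants["id"]) == ["v0"]

    # all-pass panel unchanged
    panel2 = _panel(good)
    kept2, rep2 = fg.variant_qc(panel2, RunConfig())
    assert rep2.n_kept == 1
    np.testing.assert_array_equal(kept2.dosages, panel2.dosages)


# ---------------------------------------------------------------------------
# genotype PCs
# ---------------------------------------------------------------------------

def test_pcs_separate_diverged_populations():
    """PC1 separates two populations with dAF = 0.3 over 1000 SNPs with no
    overlap at n = 500."""
    spec = SimSpec(
        n_variants=1000, seed=1, maf_bounds=(0.2, 0.8),
        populations=[PopulationSpec("A", 250, 0.0), PopulationSpec("B", 250, 0.3)],
    )
    panel, st = simulate_haplotypes(spec)
    pcs = fg.genotype_pcs(panel, 2)
    labels = st.set_index("sample").loc[pcs.index, "population"]
    a = pcs.loc[labels == "A", "PC1"]
    b = pcs.loc[labels == "B", "PC1"]
    assert a.max() < b.min() or b.max() < a.min()


def test_pcs_k0_and_orthogonality(small_cohort):
    panel = small_cohort["panel"]
    empty = fg.genotype_pcs(panel, 0)
    assert empty.shape == (panel.n_samples, 0)
    pcs = fg.genotype_pcs(panel, 4).to_numpy()
    gram = pcs.T @ pcs
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8


def test_pcs_deterministic_sign(small_cohort):
    a = fg.genotype_pcs(small_cohort["panel"], 3)
    b = fg.genotype_pcs(small_cohort["panel"], 3)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------

def test_exact_linear_phenotype():
    rng = np.random.default_rng(2)
    g = rng.binomial(2, 0.4, size=(200, 3)).astype(float)
    panel = _panel(g)
    pheno = PhenotypeMatrix(pd.DataFrame({"d": 0.5 * g[:, 1]}, index=panel.samples))
    stats = fg.gwas_linear(panel, pheno)
    row = stats.table[stats.table["SNP"] == "v1"].iloc[0]
    assert row["BETA"] == pytest.approx(0.5, abs=1e-12)
    assert row["P"] < 1e-200


def test_matches_normal_equations_oracle():
    """8-sample fixture: beta/se equal the closed-form OLS solution to
    1e-10, with and without missing dosages."""
    g = np.array([[0, 1, 2, 1, 0, 2, 1, 1], [2, 2, 1, 0, 1, 0, 1, 2]], dtype=float).T
    y = np.array([1.2, 2.1, 3.3, 2.0, 0.9, 3.8, 1.7, 2.4])
    cov = pd.DataFrame({"age": [20.0, 30, 40, 50, 60, 25, 35, 45]},
                       index=[f"s{i}" for i in range(8)])
    panel = _panel(g)
    pheno = PhenotypeMatrix(pd.DataFrame({"d": y}, index=panel.samples))
    stats = fg.gwas_linear(panel, pheno, cov, covariate_columns=["age"])
    for j in range(2):
        X = np.column_stack([g[:, j], np.ones(8), cov["age"]])
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        df = 8 - 3
        se = math.sqrt((resid @ resid) / df * XtX_inv[0, 0])
        p = 2 * t_dist.sf(abs(beta[0] / se), df)
        row = stats.table[stats.table["SNP"] == f"v{j}"].iloc[0]
        assert row["BETA"] == pytest.approx(beta[0], abs=1e-10)
        assert row["SE"] == pytest.approx(se, abs=1e-10)
        assert row["P"] == pytest.approx(p, rel=1e-8)

    # complete-case path with a missing dosage agrees with the dense oracle
    g2 = g.copy()
    g2[0, 0] = np.nan
    stats2 = fg.gwas_linear(_panel(g2), pheno, cov, covariate_columns=["age"])
    keep = np.arange(1, 8)
    X = np.column_stack([g[keep, 0], np.ones(7), cov["age"].iloc[keep]])
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y[keep]
    row = stats2.table[stats2.table["SNP"] == "v0"].iloc[0]
    assert row["N"] == 7
    assert row["BETA"] == pytest.approx(beta[0], abs=1e-10)


def test_allele_flip_negates_beta_keeps_p():
    rng = np.random.default_rng(3)
    g = rng.binomial(2, 0.3, size=(300, 1)).astype(float)
    y = 0.3 * g[:, 0] + rng.standard_normal(300)
    pheno = PhenotypeMatrix(pd.DataFrame({"d": y}, index=[f"s{i}" for i in range(300)]))
    a = fg.gwas_linear(_panel(g), pheno).table.iloc[0]
    b = fg.gwas_linear(_panel(2.0 - g), pheno).table.iloc[0]
    assert b["BETA"] == pytest.approx(-a["BETA"], abs=1e-10)
    assert b["P"] == pytest.approx(a["P"], rel=1e-10)


def test_orthogonal_covariate_leaves_beta():
    rng = np.random.default_rng(4)
    n = 400
    g = rng.binomial(2, 0.5, size=(n, 1)).astype(float)
    z = rng.standard_normal(n)
    z -= z @ (g[:, 0] - g[:, 0].mean()) / ((g[:, 0] - g[:, 0].mean()) ** 2).sum() \
        * (g[:, 0] - g[:, 0].mean())  # orthogonalize to centered dosage
    y = 0.2 * g[:, 0] + rng.standard_normal(n)
    idx = [f"s{i}" for i in range(n)]
    pheno = PhenotypeMatrix(pd.DataFrame({"d": y}, index=idx))
    cov = pd.DataFrame({"z": z}, index=idx)
    plain = fg.gwas_linear(_panel(g), pheno).table.iloc[0]
    with_cov = fg.gwas_linear(_panel(g), pheno, cov, covariate_columns=["z"]).table.iloc[0]
    assert with_cov["BETA"] == pytest.approx(plain["BETA"], abs=1e-6)


def test_null_calibration_lambda_and_type1():
    """Null scan over 5000 variants: lambda in [0.9, 1.1] and the fraction
    of p < 0.05 near 0.05."""
    rng = np.random.default_rng(5)
    n, m = 800, 5000
    g = rng.binomial(2, rng.uniform(0.1, 0.9, size=m), size=(n, m)).astype(float)
    y = rng.standard_normal(n)
    pheno = PhenotypeMatrix(pd.DataFrame({"d": y}, index=[f"s{i}" for i in range(n)]))
    stats = fg.gwas_linear(_panel(g), pheno)
    lam = stats.lambda_gc["d"]
    assert 0.9 < lam < 1.1
    frac = (stats.table["P"] < 0.05).mean()
    assert frac == pytest.approx(0.05, abs=0.01)


def test_too_few_complete_cases_reported_missing():
    g = np.full((5, 1), np.nan)
    g[:2, 0] = [0.0, 1.0]
    pheno = PhenotypeMatrix(pd.DataFrame({"d": np.arange(5.0)},
                                         index=[f"s{i}" for i in range(5)]))
    stats = fg.gwas_linear(_panel(g), pheno)
    assert np.isnan(stats.table["BETA"].iloc[0])


def test_exclude_mz_cotwins():
    cov = pd.DataFrame(
        {"zygosity": ["MZ", "MZ", "DZ", "DZ", "NA"],
         "twin_pair": ["p1", "p1", "p2", "p2", "NA"]},
        index=["a", "b", "c", "d", "e"],
    )
    keep = fg.association.exclude_mz_cotwins(cov)
    assert keep == ["a", "c", "d", "e"]
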