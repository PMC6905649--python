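"""Procrustes alignment, distance phenotypes, outlier masking, normality,
covariate adjustment, and correlation/clustering structure."""

import numpy as np
import pandas as pd
import pytest

import facegwas as fg
from facegwas.containers import LandmarkSet, PhenotypeMatrix
from facegwas.phenotype import correlation_structure
from facegwas.registry import DISTANCE_NAMES
from facegwas.simulate import TEMPLATE_FACE


def _rotz(deg):
    t = np.deg2rad(deg)
    return np.array([[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]])


# ---------------------------------------------------------------------------
# GPA
# ---------------------------------------------------------------------------

def test_gpa_similarity_invariance():
    """Copies of one shape under rotation, translation, and scaling align
    to identical configurations within 1e-8."""
    base = TEMPLATE_FACE
    shapes = np.stack([
        base,
        (base @ _rotz(37).T) + np.array([5.0, -2.0, 9.0]),
        2.0 * base,
    ])
    lms = LandmarkSet(shapes, ["a", "b", "c"])
    res = fg.gpa_align(lms)
    for i in (1, 2):
        np.testing.assert_allclose(res.aligned[i], res.aligned[0], atol=1e-8)
    assert res.residual < 1e-8


def test_gpa_identical_shapes_zero_residual():
    lms = LandmarkSet(np.stack([TEMPLATE_FACE, TEMPLATE_FACE]), ["a", "b"])
    res = fg.gpa_align(lms)
    np.testing.assert_allclose(res.aligned[0], res.aligned[1], atol=1e-12)


def test_gpa_matches_brute_force_oracle():
    """Consensus of 3 toy 4-landmark configurations equals an independent
    alternating-minimization oracle built on scipy's Kabsch solver
    (proper rotations only, matching the no-reflection convention)."""
    from scipy.spatial.transform import Rotation

    configs = np.array([
        [[0.0, 0.0, 0.0], [1.0, 0.1, 0.0], [1.1, 1.0, 0.2], [0.0, 1.2, 0.1]],
        [[0.2, 0.0, 0.1], [1.3, 0.0, 0.0], [1.0, 0.9, 0.0], [-0.1, 1.0, 0.3]],
        [[0.0, 0.1, 0.0], [0.9, -0.1, 0.1], [1.2, 1.1, 0.0], [0.1, 0.9, 0.0]],
    ])

    def norm(x):
        x = x - x.mean(axis=0)
        return x / np.sqrt((x**2).sum())

    scaled = np.stack([norm(c) for c in configs])
    # oracle: explicit alternating minimization, rotation via Kabsch
    consensus = norm(scaled.mean(axis=0))
    for _ in range(500):
        rotated = []
        for s in scaled:
            R, _ = Rotation.align_vectors(consensus, s)
            rotated.append(s @ R.as_matrix().T)
        new = norm(np.mean(rotated, axis=0))
        delta = np.linalg.norm(new - consensus)
        consensus = new
        if delta < 1e-14:
            break

    lms = LandmarkSet(configs, ["a", "b", "c"], landmark_names=("A", "B", "C", "D"))
    res = fg.gpa_align(lms, tol=1e-14, max_iter=200)
    np.testing.assert_allclose(res.consensus, consensus, atol=1e-8)


def test_gpa_idempotent():
    rng = np.random.default_rng(0)
    lms = LandmarkSet(TEMPLATE_FACE + rng.normal(0, 1, (6, 13, 3)), [f"s{i}" for i in range(6)])
    first = fg.gpa_align(lms)
    again = fg.gpa_align(LandmarkSet(first.aligned, first.samples))
    np.testing.assert_allclose(again.aligned, first.aligned, atol=1e-6)
    np.testing.assert_allclose(again.centroid_sizes, 1.0, atol=1e-12)


def test_gpa_errors():
    with pytest.raises(ValueError, match="at least 2"):
        fg.gpa_align(LandmarkSet(TEMPLATE_FACE[None], ["a"]))
    degenerate = np.stack([TEMPLATE_FACE, np.zeros((13, 3))])
    with pytest.raises(ValueError, match="degenerate.*sample 'b'"):
        fg.gpa_align(LandmarkSet(degenerate, ["a", "b"]))


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_distance_count_and_names():
    """13 landmarks produce exactly 78 = 13*12/2 named distances."""
    rng = np.random.default_rng(1)
    lms = LandmarkSet(TEMPLATE_FACE + rng.normal(0, 0.5, (4, 13, 3)), list("abcd"))
    pheno = fg.pairwise_distances(fg.gpa_align(lms))
    assert pheno.data.shape == (4, 78)
    assert tuple(pheno.data.columns) == DISTANCE_NAMES


def test_distance_is_euclidean():
    a = np.zeros((13, 3))
    a[:] = TEMPLATE_FACE
    a[0] = [0.0, 0.0, 0.0]
    a[1] = [3.0, 4.0, 0.0]
    i, j = 0, 1
    d = np.linalg.norm(a[i] - a[j])
    assert d == 5.0


def test_bilateral_symmetry_of_template():
    """On the bilaterally symmetric template, right-side distances equal
    their left-side mirrors."""
    lms = LandmarkSet(np.stack([TEMPLATE_FACE, TEMPLATE_FACE * 1.1]), ["a", "b"])
    pheno = fg.pairwise_distances(fg.gpa_align(lms))
    assert pheno.data.loc["a", "ExR-EnR"] == pytest.approx(pheno.data.loc["a", "ExL-EnL"])
    assert pheno.data.loc["a", "ExR-ChR"] == pytest.approx(pheno.data.loc["a", "ExL-ChL"])


def test_phenotype_count_formula():
    """p landmarks give p(p-1)/2 phenotype columns (p = 4 fixture)."""
    rng = np.random.default_rng(2)
    lms = LandmarkSet(rng.normal(size=(3, 4, 3)), list("abc"), landmark_names=("A", "B", "C", "D"))
    aligned = fg.gpa_align(lms)
    # direct count on aligned shapes
    n = aligned.aligned.shape[1]
    assert n * (n - 1) // 2 == 6


# ---------------------------------------------------------------------------
# outlier masking
# ---------------------------------------------------------------------------

def test_mask_outliers_z_score():
    rng = np.random.default_rng(8)
    col = np.concatenate([rng.normal(0.0, 0.1, size=29), [100.0]])
    data = pd.DataFrame({"d": col}, index=[f"s{i}" for i in range(30)])
    masked = fg.mask_outliers(PhenotypeMatrix(data), 3.0)
    # direct z-score computation: only the value 100 exceeds 3 sd
    mu, sd = col.mean(), col.std(ddof=1)
    assert abs(100 - mu) / sd > 3.0
    assert np.isnan(masked.data.loc["s29", "d"])
    assert masked.data["d"].notna().sum() == 29
    assert masked.state == "outlier-masked"


def test_mask_outliers_all_equal_and_recount(rng):
    data = pd.DataFrame({
        "const": np.ones(50),
        "noisy": rng.standard_normal(50),
    })
    data.loc[3, "noisy"] = 50.0
    masked = fg.mask_outliers(PhenotypeMatrix(data), 3.0)
    assert masked.data["const"].notna().all()
    # brute-force recount of masked cells
    expected = 0
    for col in data.columns:
        x = data[col]
        mu, sd = x.mean(), x.std(ddof=1)
        if sd > 0:
            expected += int(((x - mu).abs() > 3 * sd).sum())
    assert int(masked.data.isna().sum().sum()) == expected


def test_mask_outliers_short_column_warns():
    data = pd.DataFrame({"d": [1.0, 2.0, np.nan, np.nan, np.nan]})
    with pytest.warns(UserWarning, match="<3 non-missing"):
        masked = fg.mask_outliers(PhenotypeMatrix(data), 3.0)
    assert masked.data["d"].notna().sum() == 2


# ---------------------------------------------------------------------------
# normality
# ---------------------------------------------------------------------------

def test_check_normality(rng):
    data = pd.DataFrame({
        "gauss": rng.standard_normal(500),
        "skewed": rng.exponential(size=500),
        "tiny": [1.0, 2.0, 3.5] + [np.nan] * 497,
        "const": np.ones(500),
    })
    res = fg.check_normality(PhenotypeMatrix(data))
    assert res.loc["gauss", "W"] > 0.99
    assert res.loc["skewed", "p"] < 0.01
    assert np.isfinite(res.loc["tiny", "W"])
    assert np.isnan(res.loc["const", "W"])  # undefined, reported as such


# ---------------------------------------------------------------------------
# covariate adjustment
# ---------------------------------------------------------------------------

def test_adjust_exact_linear_dependence():
    cov = pd.DataFrame({"sex": [0, 1, 0, 1, 0, 1], "age": [20.0, 30, 40, 50, 60, 70]},
                       index=list("abcdef"))
    pheno = PhenotypeMatrix(pd.DataFrame({"d": 2.0 * cov["age"]}, index=cov.index))
    res = fg.adjust_covariates(pheno, cov)
    np.testing.assert_allclose(res.adjusted.data["d"], 0.0, atol=1e-10)
    assert res.r_squared["d"] == pytest.approx(1.0)


def test_adjust_independent_phenotype(rng):
    n = 5000
    cov = pd.DataFrame({"sex": rng.integers(0, 2, n), "age": rng.uniform(20, 70, n)},
                       index=[f"s{i}" for i in range(n)])
    pheno = PhenotypeMatrix(pd.DataFrame({"d": rng.standard_normal(n)}, index=cov.index))
    res = fg.adjust_covariates(pheno, cov)
    assert res.r_squared["d"] < 0.005


def test_adjust_matches_normal_equations_oracle():
    cov = pd.DataFrame({"sex": [0, 1, 1, 0, 1, 0], "age": [25.0, 31, 47, 52, 60, 68]},
                       index=list("abcdef"))
    y = np.array([1.2, 3.4, 2.2, 5.0, 4.1, 0.7])
    pheno = PhenotypeMatrix(pd.DataFrame({"d": y}, index=cov.index))
    res = fg.adjust_covariates(pheno, cov)
    X = np.column_stack([np.ones(6), cov["sex"], cov["age"]])
    beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
    eff = res.effects.set_index("covariate")
    assert eff.loc["sex", "beta"] == pytest.approx(beta_oracle[1], abs=1e-10)
    assert eff.loc["age", "beta"] == pytest.approx(beta_oracle[2], abs=1e-10)
    np.testing.assert_allclose(res.adjusted.data["d"], y - X @ beta_oracle, atol=1e-10)


def test_adjust_rank_deficient_errors():
    cov = pd.DataFrame({"sex": [0, 1, 0, 1], "age": [1.0, 2, 3, 4], "age2": [2.0, 4, 6, 8]},
                       index=list("abcd"))
    pheno = PhenotypeMatrix(pd.DataFrame({"d": [1.0, 2, 3, 4]}, index=cov.index))
    with pytest.raises(ValueError, match="collinear"):
        fg.adjust_covariates(pheno, cov, columns=["sex", "age", "age2"])


# ---------------------------------------------------------------------------
# correlation structure
# ---------------------------------------------------------------------------

def test_duplicated_column_merges_first(rng):
    x = rng.standard_normal(100)
    data = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.standard_normal(100),
                         "d": rng.standard_normal(100)})
    struct = correlation_structure(PhenotypeMatrix(data))
    first = struct.linkage[0]
    merged = {struct.labels[int(first[0])], struct.labels[int(first[1])]}
    assert merged == {"a", "b"}
    assert first[2] == pytest.approx(0.0, abs=1e-12)


def test_absolute_correlation_dissimilarity(rng):
    x = rng.standard_normal(2000)
    noise = rng.standard_normal(2000)
    y = -0.9 * x + np.sqrt(1 - 0.81) * noise  # r ~ -0.9
    data = pd.DataFrame({"a": x, "b": y, "c": rng.standard_normal(2000)})
    struct = correlation_structure(PhenotypeMatrix(data))
    r = struct.correlations.loc["a", "b"]
    assert r < -0.85
    # dissimilarity uses |r|: a and b merge first at height ~0.1
    first = struct.linkage[0]
    assert {struct.labels[int(first[0])], struct.labels[int(first[1])]} == {"a", "b"}
    assert first[2] == pytest.approx(1 - abs(r), abs=1e-12)


def test_clustering_matches_brute_force_agglomeration(rng):
    """Average-linkage merge tree on 4 phenotypes equals an exhaustive
    Lance-Williams agglomeration oracle."""
    data = pd.DataFrame(rng.standard_normal((60, 4)), columns=list("abcd"))
    struct = correlation_structure(PhenotypeMatrix(data))
    D = 1.0 - struct.correlations.abs().to_numpy()
    np.fill_diagonal(D, 0.0)
    # oracle: explicit average-linkage agglomeration
    clusters = {i: [i] for i in range(4)}
    dist = {frozenset((i, j)): D[i, j] for i in range(4) for j in range(i + 1, 4)}
    heights = []
    next_id = 4
    while len(clusters) > 1:
        pair = min(dist, key=lambda k: dist[k])
        h = dist[pair]
        i, j = sorted(pair)
        members = clusters.pop(i) + clusters.pop(j)
        heights.append(h)
        # brute-force recomputation over members reproduces what the
        # Lance-Williams average-linkage update maintains incrementally
        clusters[next_id] = members
        dist = {}
        ids = list(clusters)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                ca, cb = clusters[ids[ai]], clusters[ids[bi]]
                dist[frozenset((ids[ai], ids[bi]))] = float(
                    np.mean([D[x, y] for x in ca for y in cb])
                )
        next_id += 1
    np.testing.assert_allclose(sorted(struct.linkage[:, 2]), sorted(heights), atol=1e-12)


def test_zero_variance_phenotype_excluded(rng):
    data = pd.DataFrame({"a": rng.standard_normal(30), "b": rng.standard_normal(30),
                         "flat": np.ones(30)})
    with pytest.warns(UserWarning, match="zero-variance"):
        struct = correlation_structure(PhenotypeMatrix(data))
    assert struct.excluded == ["flat"]
    assert struct.labels == ["a", "b"]


def test_newick_serialization(rng):
    data = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
    nwk = correlation_structure(PhenotypeMatrix(data)).to_newick()
    assert nwk.endswith(";") and nwk.count("(") == 2
    for label in "abc":
        assert label in nwk
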